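import pytest

from gistprev import default_parameter_table, parameter_set_from_table


@pytest.fixture(scope="session")
def table():
    return default_parameter_table()


@pytest.fixture(scope="session")
def base_params(table):
    return parameter_set_from_table(table)
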