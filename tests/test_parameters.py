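"""Unit conversions, moment matching and the registry-facing computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gistprev import (
    IncidenceStratum,
    LifeTableRow,
    ModelParameter,
    ParameterSet,
    beta_from_mean_se,
    gamma_from_mean_se,
    median_to_rate,
    rate_to_annual_prob,
    rate_to_median,
    standardize_incidence,
    weighted_background_mortality,
)
from gistprev.parameters import (
    annual_prob_to_rate,
    read_incidence_strata,
    read_life_table,
    write_incidence_strata,
    write_life_table,
)


@pytest.mark.parametrize(
    "median, rate",
    [(math.log(2), 1.0), (0.77, 0.90019), (2.0, 0.34657), (1.5, 0.46210)],
)
def test_median_to_rate(median, rate):
    assert median_to_rate(median) == pytest.approx(rate, abs=1e-5)


@given(st.floats(min_value=1e-3, max_value=1e3))
@settings(derandomize=True, deadline=None)
def test_median_rate_round_trip(median):
    assert rate_to_median(median_to_rate(median)) == pytest.approx(median, rel=1e-12)


@pytest.mark.parametrize(
    "rate, prob", [(0.0, 0.0), (math.log(2), 0.5), (0.904, 0.59505)]
)
def test_rate_to_annual_prob(rate, prob):
    assert rate_to_annual_prob(rate) == pytest.approx(prob, abs=1e-5)


@given(st.floats(min_value=0, max_value=50))
@settings(derandomize=True, deadline=None)
def test_annual_prob_bounded_and_invertible(rate):
    p = rate_to_annual_prob(rate)
    assert 0 <= p <= 1  # p < 1 mathematically; rounds to 1.0 beyond ~rate 37
    if rate <= 10:  # inverse loses precision as p approaches 1
        assert p < 1
        assert annual_prob_to_rate(p) == pytest.approx(rate, rel=1e-7, abs=1e-12)


def test_annual_prob_small_rate_taylor():
    # p ~ r to first order for tiny rates
    assert rate_to_annual_prob(5e-5) == pytest.approx(5e-5, rel=1e-4)


@pytest.mark.parametrize("bad_call", [
    lambda: median_to_rate(0.0),
    lambda: median_to_rate(-1.0),
    lambda: rate_to_annual_prob(-0.1),
    lambda: annual_prob_to_rate(1.0),
    lambda: gamma_from_mean_se(0.0, 1.0),
    lambda: gamma_from_mean_se(1.0, 0.0),
    lambda: beta_from_mean_se(1.2, 0.1),
    lambda: beta_from_mean_se(0.5, 0.6),  # se^2 >= mean(1-mean)
])
def test_domain_errors(bad_call):
    with pytest.raises(ValueError):
        bad_call()


@pytest.mark.parametrize(
    "mean, se, shape, scale",
    [
        (1.0, 1.0, 1.0, 1.0),
        (0.351, 0.103, 11.613, 0.030225),
        (1.053e-5, 1.39e-6, 57.388, 1.8348e-7),
    ],
)
def test_gamma_moment_matching(mean, se, shape, scale):
    sh, sc = gamma_from_mean_se(mean, se)
    assert sh == pytest.approx(shape, rel=1e-4)
    assert sc == pytest.approx(scale, rel=1e-4)
    assert sh * sc == pytest.approx(mean, rel=1e-12)
    assert math.sqrt(sh) * sc == pytest.approx(se, rel=1e-12)


@pytest.mark.parametrize(
    "mean, se, alpha, beta",
    [(0.5, 0.25, 1.5, 1.5), (0.8, 0.05, 50.4, 12.6)],
)
def test_beta_moment_matching(mean, se, alpha, beta):
    a, b = beta_from_mean_se(mean, se)
    assert a == pytest.approx(alpha, rel=1e-9)
    assert b == pytest.approx(beta, rel=1e-9)


@pytest.mark.parametrize(
    "family, mean, se",
    [("gamma", 0.351, 0.103), ("gamma", 1.053e-5, 1.39e-6), ("beta", 0.8, 0.05)],
)
def test_sampling_recovers_moments(family, mean, se):
    """1e5 draws from the matched distribution recover mean and SD."""
    rng = np.random.default_rng(12345)
    n = 100_000
    if family == "gamma":
        shape, scale = gamma_from_mean_se(mean, se)
        x = rng.gamma(shape, scale, size=n)
    else:
        a, b = beta_from_mean_se(mean, se)
        x = rng.beta(a, b, size=n)
    mc_se_mean = se / math.sqrt(n)
    assert abs(x.mean() - mean) < 3 * mc_se_mean
    # SD of the sample SD ~ se / sqrt(2(n-1)) times sqrt(1 + excess kurtosis/2);
    # a factor-3 cushion over the normal-theory value covers the skew here
    assert abs(x.std(ddof=1) - se) < 9 * se / math.sqrt(2 * (n - 1))


class TestStandardizeIncidence:
    def _stratum(self, cases, py, ref, band="60-69", sex="M"):
        return IncidenceStratum(band, sex, cases, py, ref)

    def test_single_stratum_is_crude_rate(self):
        assert standardize_incidence([self._stratum(10, 1e6, 123.0)]) == pytest.approx(1e-5)

    def test_equal_weights_average(self):
        strata = [
            self._stratum(10, 1e6, 1.0),
            self._stratum(30, 1e6, 1.0, band="70-79"),
        ]
        assert standardize_incidence(strata) == pytest.approx(2e-5)

    def test_invariant_to_splitting_a_stratum(self):
        whole = [self._stratum(20, 2e6, 8.0), self._stratum(5, 1e6, 2.0, sex="F")]
        halves = [
            self._stratum(10, 1e6, 4.0),
            self._stratum(10, 1e6, 4.0),
            self._stratum(5, 1e6, 2.0, sex="F"),
        ]
        assert standardize_incidence(halves) == pytest.approx(
            standardize_incidence(whole), rel=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            standardize_incidence([])
        with pytest.raises(ValueError):
            standardize_incidence([self._stratum(1, 1e6, 0.0)])


class TestWeightedBackgroundMortality:
    def test_single_band_identity(self):
        q = -math.expm1(-0.0314)
        rows = [LifeTableRow("all", q, 1.0)]
        assert weighted_background_mortality(rows) == pytest.approx(0.0314, rel=1e-12)

    def test_two_band_mean_on_rate_scale(self):
        rows = [
            LifeTableRow("a", -math.expm1(-0.01), 0.5),
            LifeTableRow("b", -math.expm1(-0.05), 0.5),
        ]
        assert weighted_background_mortality(rows) == pytest.approx(0.03, rel=1e-12)

    def test_unnormalized_weights_are_normalized(self):
        rows = [
            LifeTableRow("a", -math.expm1(-0.01), 2.0),
            LifeTableRow("b", -math.expm1(-0.05), 2.0),
        ]
        assert weighted_background_mortality(rows) == pytest.approx(0.03, rel=1e-12)

    def test_certain_death_rejected(self):
        with pytest.raises(ValueError):
            weighted_background_mortality([LifeTableRow("x", 1.0, 1.0)])


class TestContainers:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameter("x", base=2.0, se=0.1, min=0.0, max=1.0, family="gamma")
        with pytest.raises(ValueError):
            ModelParameter("x", base=0.5, se=0.6, min=0.0, max=1.0, family="beta")
        with pytest.raises(ValueError):
            ModelParameter("x", base=0.5, se=0.1, min=0.0, max=1.0, family="weibull")

    def test_fixed_copy_pins_value(self):
        p = ModelParameter("x", base=0.5, se=0.1, min=0.2, max=0.9, family="gamma")
        f = p.fixed(1.2)
        assert f.family == "fixed" and f.base == 1.2 and f.se == 0.0
        assert f.min <= 1.2 <= f.max

    def test_parameter_set_validation(self, base_params):
        with pytest.raises(ValueError):
            base_params.replace(incidence=0.0)
        with pytest.raises(ValueError):
            base_params.replace(p_resectable=1.0)

    def test_default_table_is_complete(self, table, base_params):
        assert set(table) == set(base_params.as_dict())
        assert table["p_resectable"].family == "beta"
        assert base_params.population == 62_262_100


def test_csv_round_trips(tmp_path):
    strata = [IncidenceStratum("60-69", "F", 12, 1.25e6, 4.0e6)]
    rows = [LifeTableRow("60-69", 0.01, 0.3), LifeTableRow("70-79", 0.03, 0.7)]
    write_incidence_strata(strata, tmp_path / "s.csv")
    write_life_table(rows, tmp_path / "l.csv")
    assert read_incidence_strata(tmp_path / "s.csv") == strata
    assert read_life_table(tmp_path / "l.csv") == rows
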