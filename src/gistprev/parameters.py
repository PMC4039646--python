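"""Model parameters, unit conversions and distribution moment-matching.

The prevalence model is driven by seven quantities: the GIST incidence
(per person-year), the proportion of newly diagnosed disease that is
resectable, four annual state-exit rates (post-resection relapse,
imatinib failure, sunitinib failure, third-line exit) and a yearly
background-mortality rate.  Each is carried as a :class:`ModelParameter`
with a base value, a standard error and a min-max range for one-way
sensitivity analysis; the complete model input is a :class:`ParameterSet`.

All survival inputs are treated as exponential time-to-event quantities,
so a median survival of ``m`` years corresponds to an exit rate of
``ln(2)/m`` per year, and an annual rate ``r`` to an annual transition
probability ``1 - exp(-r)``.

This module also implements the two registry-facing computations the
model's inputs are built from: direct age/sex standardization of
stratified incidence counts, and life-table background mortality weighted
by the patient age distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ModelParameter",
    "ParameterSet",
    "IncidenceStratum",
    "LifeTableRow",
    "PARAMETER_NAMES",
    "UK_POPULATION_2010",
    "median_to_rate",
    "rate_to_median",
    "rate_to_annual_prob",
    "annual_prob_to_rate",
    "gamma_from_mean_se",
    "beta_from_mean_se",
    "standardize_incidence",
    "weighted_background_mortality",
    "load_parameter_table",
    "default_parameter_table",
    "parameter_set_from_table",
    "read_incidence_strata",
    "write_incidence_strata",
    "read_life_table",
    "write_life_table",
]

#: Estimated total UK population in 2010, the open-population denominator.
UK_POPULATION_2010 = 62_262_100

#: Canonical ordering of the seven model parameters.
PARAMETER_NAMES = (
    "incidence",
    "p_resectable",
    "relapse_rate",
    "imatinib_failure_rate",
    "sunitinib_failure_rate",
    "thirdline_exit_rate",
    "background_mortality",
)

_FAMILIES = ("gamma", "beta", "fixed")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def median_to_rate(median_years: float) -> float:
    """Annual exit rate implied by an exponential median survival.

    Parameters
    ----------
    median_years
        Median time-to-event in years; must be positive.

    Returns
    -------
    float
        Rate ``ln(2) / median_years`` per year.
    """
    if median_years <= 0:
        raise ValueError(f"median must be positive, got {median_years}")
    return math.log(2.0) / median_years


def rate_to_median(rate: float) -> float:
    """Median survival (years) of an exponential with the given annual rate."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return math.log(2.0) / rate


def rate_to_annual_prob(rate: float) -> float:
    """Annual transition probability ``1 - exp(-rate)`` for a yearly rate.

    Keeps the annual difference equations stable even when competing
    rates sum above 1 (probabilities stay in ``[0, 1)``).
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    return -math.expm1(-rate)


def annual_prob_to_rate(prob: float) -> float:
    """Inverse of :func:`rate_to_annual_prob`; requires ``0 <= prob < 1``."""
    if not 0 <= prob < 1:
        raise ValueError(f"probability must be in [0, 1), got {prob}")
    return -math.log1p(-prob)


# ---------------------------------------------------------------------------
# moment matching for PSA distributions
# ---------------------------------------------------------------------------

def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matched to a mean and standard error.

    ``shape = (mean/se)**2`` and ``scale = se**2/mean``, the standard
    method-of-moments parameterization used for strictly positive rates.
    """
    if mean <= 0 or se <= 0:
        raise ValueError(f"mean and se must be positive, got mean={mean}, se={se}")
    return (mean / se) ** 2, se**2 / mean


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) matched to a mean and standard error.

    Uses ``nu = mean*(1-mean)/se**2 - 1`` with ``alpha = mean*nu`` and
    ``beta = (1-mean)*nu``.  The variance must be achievable, i.e.
    ``se**2 < mean*(1-mean)``.
    """
    if not 0 < mean < 1:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise ValueError(
            f"se={se} too large for a beta with mean {mean} "
            f"(requires se^2 < {mean * (1 - mean):.4g})"
        )
    return mean * nu, (1.0 - mean) * nu


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameter:
    """One named model quantity with uncertainty specification.

    ``family`` selects the PSA sampling distribution: ``gamma`` for
    rates/incidence, ``beta`` for proportions, ``fixed`` to pin the
    parameter at its base value (used for scenario overrides).
    """

    name: str
    base: float
    se: float
    min: float
    max: float
    family: str

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.se < 0:
            raise ValueError(f"{self.name}: se must be nonnegative")
        if not self.min <= self.base <= self.max:
            raise ValueError(
                f"{self.name}: base {self.base} outside [{self.min}, {self.max}]"
            )
        if self.family == "beta":
            if not 0 <= self.base <= 1:
                raise ValueError(f"{self.name}: beta base must lie in [0, 1]")
            if self.se > 0 and self.se**2 >= self.base * (1 - self.base):
                raise ValueError(f"{self.name}: se too large for beta moments")
        if self.family == "gamma" and self.se > 0 and self.base <= 0:
            raise ValueError(f"{self.name}: gamma base must be positive")

    def with_base(self, base: float) -> "ModelParameter":
        """Copy with a new base value, clipping the SA range to contain it."""
        return replace(
            self, base=base, min=min(self.min, base), max=max(self.max, base)
        )

    def fixed(self, value: float | None = None) -> "ModelParameter":
        """Copy pinned at ``value`` (default: current base) with family=fixed."""
        base = self.base if value is None else value
        return replace(
            self,
            base=base,
            se=0.0,
            min=min(self.min, base),
            max=max(self.max, base),
            family="fixed",
        )


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input: the seven parameters plus the population size."""

    incidence: float
    p_resectable: float
    relapse_rate: float
    imatinib_failure_rate: float
    sunitinib_failure_rate: float
    thirdline_exit_rate: float
    background_mortality: float
    population: float = UK_POPULATION_2010

    def __post_init__(self) -> None:
        for name in (
            "incidence",
            "relapse_rate",
            "imatinib_failure_rate",
            "sunitinib_failure_rate",
            "thirdline_exit_rate",
            "background_mortality",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.p_resectable < 1:
            raise ValueError("p_resectable must lie strictly in (0, 1)")
        if self.population <= 0:
            raise ValueError("population must be positive")

    def replace(self, **overrides: float) -> "ParameterSet":
        return replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


# ---------------------------------------------------------------------------
# registry-style inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidenceStratum:
    """Registry incidence in one age/sex stratum plus its reference weight."""

    age_band: str
    sex: str
    cases: int
    person_years: float
    reference_population: float

    def __post_init__(self) -> None:
        if self.cases < 0:
            raise ValueError("cases must be nonnegative")
        if self.person_years <= 0:
            raise ValueError("person_years must be positive")
        if self.reference_population < 0:
            raise ValueError("reference_population must be nonnegative")

    @property
    def rate(self) -> float:
        return self.cases / self.person_years


@dataclass(frozen=True)
class LifeTableRow:
    """One life-table age band with its patient-age weight."""

    age_band: str
    annual_mortality: float
    patient_weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.annual_mortality <= 1:
            raise ValueError("annual_mortality must lie in [0, 1]")
        if self.patient_weight < 0:
            raise ValueError("patient_weight must be nonnegative")


def standardize_incidence(strata: Sequence[IncidenceStratum]) -> float:
    """Direct-standardized incidence over age/sex strata.

    Applies each stratum's crude rate to the reference population and
    returns the reference-weighted mean rate (per person-year).
    """
    if not strata:
        raise ValueError("need at least one stratum")
    total_ref = sum(s.reference_population for s in strata)
    if total_ref <= 0:
        raise ValueError("reference populations must sum to a positive total")
    return sum(s.rate * s.reference_population for s in strata) / total_ref


def weighted_background_mortality(rows: Sequence[LifeTableRow]) -> float:
    """Patient-age-weighted background mortality rate (per year).

    Life-table annual death probabilities are converted to rates
    (``-ln(1 - q)``) before weighting, so the result composes correctly
    with the disease-exit rates of the model.
    """
    if not rows:
        raise ValueError("need at least one life-table row")
    total_w = sum(r.patient_weight for r in rows)
    if total_w <= 0:
        raise ValueError("patient weights must sum to a positive total")
    acc = 0.0
    for r in rows:
        if r.annual_mortality >= 1.0:
            raise ValueError(f"{r.age_band}: annual mortality of 1 has infinite rate")
        acc += (r.patient_weight / total_w) * -math.log1p(-r.annual_mortality)
    return acc


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_parameter_table(path: str | Path) -> dict[str, ModelParameter]:
    """Load a parameter table from a YAML file (name -> base/se/min/max/family)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _table_from_mapping(raw)


def default_parameter_table() -> dict[str, ModelParameter]:
    """The packaged default parameter table (UK base case)."""
    text = resources.files("gistprev").joinpath("data/table1.yml").read_text()
    return _table_from_mapping(yaml.safe_load(text))


def _table_from_mapping(raw: Mapping[str, Mapping[str, object]]) -> dict[str, ModelParameter]:
    unknown = set(raw) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    missing = set(PARAMETER_NAMES) - set(raw)
    if missing:
        raise ValueError(f"missing parameters: {sorted(missing)}")
    table = {}
    for name in PARAMETER_NAMES:
        spec = raw[name]
        table[name] = ModelParameter(
            name=name,
            base=float(spec["base"]),
            se=float(spec["se"]),
            min=float(spec["min"]),
            max=float(spec["max"]),
            family=str(spec["family"]),
        )
    return table


def parameter_set_from_table(
    table: Mapping[str, ModelParameter],
    population: float = UK_POPULATION_2010,
) -> ParameterSet:
    """Base-case :class:`ParameterSet` from a parameter table."""
    return ParameterSet(
        population=population, **{name: table[name].base for name in PARAMETER_NAMES}
    )


_STRATA_COLS = ["age_band", "sex", "cases", "person_years", "reference_population"]
_LIFE_COLS = ["age_band", "annual_mortality", "patient_weight"]


def read_incidence_strata(path: str | Path) -> list[IncidenceStratum]:
    df = pd.read_csv(path, dtype={"age_band": str, "sex": str})
    return [
        IncidenceStratum(
            age_band=row.age_band,
            sex=row.sex,
            cases=int(row.cases),
            person_years=float(row.person_years),
            reference_population=float(row.reference_population),
        )
        for row in df[_STRATA_COLS].itertuples(index=False)
    ]


def write_incidence_strata(strata: Iterable[IncidenceStratum], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in strata])[_STRATA_COLS].to_csv(path, index=False)


def read_life_table(path: str | Path) -> list[LifeTableRow]:
    df = pd.read_csv(path, dtype={"age_band": str})
    return [
        LifeTableRow(
            age_band=row.age_band,
            annual_mortality=float(row.annual_mortality),
            patient_weight=float(row.patient_weight),
        )
        for row in df[_LIFE_COLS].itertuples(index=False)
    ]


def write_life_table(rows: Iterable[LifeTableRow], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows])[_LIFE_COLS].to_csv(path, index=False)
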