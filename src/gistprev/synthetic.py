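"""Synthetic registry and life-table fixtures.

The model's two data-derived inputs — a direct-standardized incidence
and a patient-age-weighted background mortality — are built in practice
from a cancer-registry extract and national life tables.  Neither is
shipped; this module generates statistically realistic stand-ins:

* stratified incidence counts: Poisson case counts over person-years in
  10-year age bands by sex, with a log-linear age gradient calibrated so
  the direct-standardized rate has expectation ``true_overall_incidence``;
* a life table with a Gompertz-like (geometric per-band) mortality
  schedule and a patient age distribution skewed to older bands,
  calibrated so the weighted background mortality centres on 0.0314/y;
* uniformly random valid parameter sets over the one-way SA ranges, for
  property tests.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    IncidenceStratum,
    LifeTableRow,
    ModelParameter,
    ParameterSet,
    UK_POPULATION_2010,
    default_parameter_table,
)

__all__ = [
    "SyntheticConfig",
    "generate_incidence_strata",
    "generate_life_table",
    "random_parameter_set",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the fixture generators.

    ``incidence_gradient`` and ``mortality_gradient`` are per-age-band
    multipliers (10-year bands); mortality roughly doubles per decade of
    adult age, and rare GI-tract tumour incidence rises steeply with age.
    """

    seed: int = 0
    n_age_bands: int = 9
    true_overall_incidence: float = 1.053e-5
    person_years_per_stratum: float = 1.25e6
    incidence_gradient: float = 1.6
    mortality_gradient: float = 2.0
    mortality_target: float = 0.0314
    mortality_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_age_bands < 1:
            raise ValueError("need at least one age band")
        if self.person_years_per_stratum <= 0:
            raise ValueError("person_years_per_stratum must be positive")
        if self.true_overall_incidence <= 0:
            raise ValueError("true_overall_incidence must be positive")


def _age_bands(n: int) -> list[str]:
    bands = [f"{10 * i}-{10 * i + 9}" for i in range(n - 1)]
    bands.append(f"{10 * (n - 1)}+")
    return bands


# UK-like population share by 10-year band (young-heavy, thinning at old age)
_REF_SHAPE = np.array([12.0, 12.0, 13.0, 14.0, 14.0, 13.0, 11.0, 7.0, 4.0])


def _reference_weights(n: int) -> np.ndarray:
    shape = np.resize(_REF_SHAPE, n) if n > len(_REF_SHAPE) else _REF_SHAPE[:n]
    return shape / shape.sum()


def generate_incidence_strata(cfg: SyntheticConfig) -> list[IncidenceStratum]:
    """Poisson registry counts by age band and sex.

    Stratum rates follow ``c * incidence_gradient**band`` (constant within
    a band), with a mild male excess, and ``c`` solved so that the
    reference-weighted mean of the true rates equals
    ``cfg.true_overall_incidence`` — hence the direct-standardized rate of
    a generated table is unbiased for it.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_age_bands
    bands = _age_bands(n)
    ref_w = _reference_weights(n)

    shape = cfg.incidence_gradient ** np.arange(n)
    sex_mult = {"M": 1.2, "F": 0.8}  # averages to 1 under an even sex split
    # reference-weighted mean of true rates across both sexes
    mean_shape = float((ref_w * shape).sum())  # sex multipliers average out
    c = cfg.true_overall_incidence / mean_shape

    strata = []
    for sex in ("M", "F"):
        for i, band in enumerate(bands):
            rate = c * shape[i] * sex_mult[sex]
            cases = int(rng.poisson(rate * cfg.person_years_per_stratum))
            strata.append(
                IncidenceStratum(
                    age_band=band,
                    sex=sex,
                    cases=cases,
                    person_years=cfg.person_years_per_stratum,
                    reference_population=float(
                        0.5 * ref_w[i] * UK_POPULATION_2010
                    ),
                )
            )
    return strata


# patient age distribution: GIST presents mostly in the 60s-70s
def _patient_weights(n: int) -> np.ndarray:
    centres = np.arange(n, dtype=float)
    w = np.exp(-0.5 * ((centres - 6.5) / 1.5) ** 2)
    return w / w.sum()


def generate_life_table(cfg: SyntheticConfig) -> list[LifeTableRow]:
    """Life table whose patient-weighted mortality centres on the target.

    Band mortality rates follow ``r0 * mortality_gradient**band`` with
    ``r0`` solved so the patient-weighted rate equals
    ``cfg.mortality_target`` before jitter; a small lognormal jitter
    (sd ``mortality_jitter_sd`` on the log scale) makes each seed's table
    distinct while staying near the target.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_age_bands
    w = _patient_weights(n)
    shape = cfg.mortality_gradient ** np.arange(n)
    r0 = cfg.mortality_target / float((w * shape).sum())
    rates = r0 * shape * np.exp(rng.normal(0.0, cfg.mortality_jitter_sd, size=n))
    return [
        LifeTableRow(
            age_band=band,
            annual_mortality=float(-np.expm1(-rate)),
            patient_weight=float(w[i]),
        )
        for i, (band, rate) in enumerate(zip(_age_bands(n), rates))
    ]


def random_parameter_set(
    seed: int | np.random.Generator,
    table: dict[str, ModelParameter] | None = None,
    population: float = UK_POPULATION_2010,
) -> ParameterSet:
    """Uniform draw of every parameter within its one-way SA range."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = table if table is not None else default_parameter_table()
    values = {name: float(rng.uniform(p.min, p.max)) for name, p in table.items()}
    return ParameterSet(population=population, **values)
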