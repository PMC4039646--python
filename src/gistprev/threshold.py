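"""Threshold analysis against the ultra-orphan prevalence boundary.

Finds the parameter value at which equilibrium third-line prevalence
reaches a target (by default 2 per 100,000, the NICE ultra-orphan
boundary), holding every other parameter at its base-case value.  Two
parameters are supported: the GIST incidence — where equilibrium counts
are exactly linear, so the threshold is a rescaling — and the
third-line exit rate, where the crossing is found by root bracketing.

Note the direction for the exit rate: prevalence *falls* as the rate
rises (a higher exit rate means shorter third-line survival), so the
prevalence exceeds the target for rates at or *below* the crossing
value, i.e. for median survival at or above the implied median.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .model import closed_form_equilibrium, outcomes
from .parameters import ParameterSet, rate_to_median

__all__ = ["ThresholdResult", "threshold_incidence", "threshold_thirdline_rate"]


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    threshold_value: float
    target_prevalence: float
    bracket: tuple[float, float]
    implied_median_years: float | None = None


def _thirdline_prev(params: ParameterSet) -> float:
    return outcomes(closed_form_equilibrium(params), params).thirdline_prev_per_100k


def threshold_incidence(
    params: ParameterSet, target: float = 2.0, method: str = "linear"
) -> ThresholdResult:
    """Incidence at which equilibrium third-line prevalence equals ``target``.

    All equilibrium occupancies are homogeneous of degree one in the
    incidence, so the threshold is ``incidence * target / prevalence``;
    a bisection fallback (``method='bisect'``) is provided as a
    cross-check.  The result is verified by re-evaluating the model.
    """
    base_prev = _thirdline_prev(params)
    if base_prev <= 0:
        raise ValueError("base-case third-line prevalence is zero; no threshold")
    if target <= 0:
        raise ValueError("target prevalence must be positive")

    if method == "linear":
        gamma_star = params.incidence * target / base_prev
    elif method == "bisect":
        scale = target / base_prev
        lo, hi = params.incidence * scale * 0.5, params.incidence * scale * 2.0
        gamma_star = brentq(
            lambda g: _thirdline_prev(params.replace(incidence=g)) - target,
            lo,
            hi,
            xtol=1e-16,
            rtol=1e-14,
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    check = _thirdline_prev(params.replace(incidence=gamma_star))
    assert abs(check - target) < 1e-6, "threshold re-evaluation failed"
    return ThresholdResult(
        parameter="incidence",
        threshold_value=gamma_star,
        target_prevalence=target,
        bracket=(0.0, float("inf")) if method == "linear" else (lo, hi),
    )


def threshold_thirdline_rate(
    params: ParameterSet,
    target: float = 2.0,
    bracket: tuple[float, float] = (0.01, 5.0),
    tol: float = 1e-6,
) -> ThresholdResult:
    """Third-line exit rate at which equilibrium prevalence equals ``target``.

    Prevalence is continuous and strictly decreasing in the exit rate, so
    the crossing is unique when it exists.  The bracket is widened
    automatically; a target above the attainable supremum (the prevalence
    as the exit rate tends to zero, where only background mortality
    empties the state) raises an error naming that supremum.
    """
    if target <= 0:
        raise ValueError("target prevalence must be positive")

    def prev_minus_target(rate: float) -> float:
        return _thirdline_prev(params.replace(thirdline_exit_rate=rate)) - target

    lo, hi = bracket
    # widen until the target is bracketed (prevalence decreasing in rate)
    for _ in range(60):
        if prev_minus_target(lo) >= 0:
            break
        lo /= 2.0
        if lo < 1e-12:
            sup = _thirdline_prev(params.replace(thirdline_exit_rate=1e-12))
            raise ValueError(
                f"target {target} per 100,000 unattainable: supremum of the "
                f"third-line prevalence is {sup:.4f} per 100,000"
            )
    for _ in range(60):
        if prev_minus_target(hi) <= 0:
            break
        hi *= 2.0
    else:
        # prevalence has a positive limit as the exit rate grows without
        # bound (background mortality alone cannot empty the state faster)
        inf_prev = target + prev_minus_target(hi)
        raise ValueError(
            f"target {target} per 100,000 unattainable: infimum of the "
            f"third-line prevalence is {inf_prev:.4f} per 100,000"
        )

    rate_star = brentq(prev_minus_target, lo, hi, xtol=1e-14, rtol=1e-15)
    assert abs(prev_minus_target(rate_star)) < tol, "threshold re-evaluation failed"
    return ThresholdResult(
        parameter="thirdline_exit_rate",
        threshold_value=rate_star,
        target_prevalence=target,
        bracket=(lo, hi),
        implied_median_years=rate_to_median(rate_star),
    )
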