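"""Reaction-rate estimation and mass-balance summaries for adjusted curves.

First-order rates come from ordinary least squares of ln(adjusted) on time
(the semi-log plot of a first-order process is a straight line whose slope is
the signed rate, 1/time; negative = removal).  Zero-order rates come from OLS
of the adjusted concentration on time (slope in concentration/time).  Both
report the 95% confidence half-width from the t-distribution with n-2 degrees
of freedom and the two-sided p-value of the slope; the *reported* rate is set
to 0 when the slope is not significant at p < 0.05, mirroring common field
reporting practice, while the raw estimate is always retained.

Recovery factors integrate the dilution-adjusted concentration over extracted
volume (trapezoid rule — exact for the piecewise-linear profiles plotted) and
compare against the injected concentration times total extracted volume:
RF > 1 indicates net production, RF < 1 net removal, RF = 1 no net change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .model import AdjustedSeries, PushPullError

__all__ = [
    "RateFit",
    "RecoveryResult",
    "InsufficientDataError",
    "fit_first_order",
    "fit_zero_order",
    "recovery_factor",
    "net_mass_change",
    "volume_from_rate",
]

# Residual sum of squares below this fraction of the data's scale counts as a
# perfect fit; inference then reports p = 0 and a zero CI instead of 0/0 NaNs.
_PERFECT_FIT_RTOL = 1e-12


class InsufficientDataError(PushPullError):
    """Fewer than three usable samples, or no time variation, for a regression."""


@dataclass(frozen=True)
class RateFit:
    """OLS slope estimate of a kinetic model with its inference.

    ``rate`` is the signed slope (1/time for first-order, concentration/time
    for zero-order).  ``reported_rate`` is ``rate`` when p < 0.05 and 0.0
    otherwise.  ``n`` counts the samples used; ``n_excluded`` counts
    nonpositive samples dropped before a log-scale fit.
    """

    model: Literal["zero_order", "first_order"]
    rate: float
    ci95_halfwidth: float
    p_value: float
    reported_rate: float
    n: int
    intercept: float
    n_excluded: int = 0


@dataclass(frozen=True)
class RecoveryResult:
    """Mass balance of one adjusted curve over the pull phase.

    ``recovery_factor`` (RF) is the adjusted-curve integral over extracted
    volume divided by Ci * V_total; ``net_mass_change`` is the same integral
    minus Ci * V_total, so RF = 1 exactly when the net change is zero.
    """

    recovery_factor: float
    net_mass_change: float
    v_extracted_total: float


def _ols_with_inference(
    t: np.ndarray, y: np.ndarray, model: Literal["zero_order", "first_order"],
    n_excluded: int = 0,
) -> RateFit:
    n = t.size
    if n < 3:
        raise InsufficientDataError(
            f"{model} fit needs >= 3 usable samples, got {n}"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError(f"{model} fit needs time variation; all t equal")
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    sse = float(np.sum((y - fitted) ** 2))
    scale = max(float(np.sum(y * y)), 1.0)
    if sse <= _PERFECT_FIT_RTOL * scale:
        # Degenerate exact fit: zero residual variance, no sampling uncertainty.
        ci, p = 0.0, 0.0
    else:
        tcrit = float(stats.t.ppf(0.975, n - 2))
        ci = tcrit * float(res.stderr)
        p = float(res.pvalue)
    rate = float(res.slope)
    return RateFit(
        model=model,
        rate=rate,
        ci95_halfwidth=ci,
        p_value=p,
        reported_rate=rate if p < 0.05 else 0.0,
        n=n,
        intercept=float(res.intercept),
        n_excluded=n_excluded,
    )


def fit_first_order(adj: AdjustedSeries) -> RateFit:
    """First-order rate from OLS of ln(adjusted concentration) on time.

    Nonpositive adjusted values cannot be log-transformed; they are excluded
    with a warning reporting the count.  Unweighted on the log scale.
    """
    mask = adj.adjusted > 0
    n_excluded = int(np.sum(~mask))
    if n_excluded:
        warnings.warn(
            f"first-order fit for {adj.solute!r}: excluded {n_excluded} "
            "nonpositive adjusted sample(s) from the log-scale regression",
            stacklevel=2,
        )
    return _ols_with_inference(
        adj.time[mask], np.log(adj.adjusted[mask]), "first_order", n_excluded
    )


def fit_zero_order(adj: AdjustedSeries) -> RateFit:
    """Zero-order rate from OLS of the adjusted concentration on time."""
    return _ols_with_inference(adj.time, adj.adjusted, "zero_order")


def volume_from_rate(time: np.ndarray, extraction_rate: float) -> np.ndarray:
    """Cumulative extracted volume under a constant extraction rate.

    A convenience for tests recorded without flow totals; recovery factors are
    invariant to the constant chosen, net mass change scales with it.
    """
    if not extraction_rate > 0:
        raise PushPullError(f"extraction_rate must be > 0, got {extraction_rate}")
    return np.asarray(time, dtype=float) * extraction_rate


def _integrate(adj: AdjustedSeries, volume) -> tuple[float, float]:
    if volume is None:
        raise PushPullError(
            "recovery computations need cumulative extracted volumes; none were "
            "given — either record volumes or derive them with "
            "volume_from_rate(time, extraction_rate) under a constant-rate "
            "assumption"
        )
    v = np.asarray(volume, dtype=float)
    if v.size != adj.time.size:
        raise PushPullError(
            f"volume has {v.size} samples but the adjusted series has "
            f"{adj.time.size}"
        )
    if v.size < 2 or np.any(np.diff(v) < 0) or not np.ptp(v) > 0:
        raise PushPullError(
            "volume must be nondecreasing with positive total extracted volume"
        )
    if not adj.c_injection > 0:
        raise PushPullError(
            f"recovery factor undefined: c_injection = {adj.c_injection}"
        )
    integral = float(np.trapezoid(adj.adjusted, v))
    v_total = float(v[-1] - v[0])
    return integral, v_total


def recovery_factor(adj: AdjustedSeries, volume) -> RecoveryResult:
    """Recovery factor and net mass change of an adjusted breakthrough curve.

    RF = integral(adjusted dV) / (Ci * V_total).  A nonreactive solute adjusted
    against itself gives RF = 1 identically; RF > 1 flags net production and
    RF < 1 net removal over the pull phase.
    """
    integral, v_total = _integrate(adj, volume)
    baseline = adj.c_injection * v_total
    return RecoveryResult(
        recovery_factor=integral / baseline,
        net_mass_change=integral - baseline,
        v_extracted_total=v_total,
    )


def net_mass_change(adj: AdjustedSeries, volume) -> float:
    """Net mass produced (+) or removed (-) over the pull phase.

    The adjusted-curve integral over extracted volume minus the injected
    concentration times the total extracted volume.
    """
    integral, v_total = _integrate(adj, volume)
    return integral - adj.c_injection * v_total
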