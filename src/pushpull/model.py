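"""Domain types and dilution-adjustment methods for single-well push-pull tests.

A push-pull test injects a prepared fluid containing nonreactive (conservative)
and reactive solutes into a well, then extracts groundwater from the same well.
The extracted fluid is a mixture of injection and aquifer fluids, so the raw
breakthrough curve of a reactive solute confounds dilution with reaction.  Two
adjustments are implemented:

* the **conventional** method, ``Ce2* = Ce2 * Ci1 / Ce1``, which rescales the
  reactive solute by the relative change of the tracer and is valid only when
  the injection/aquifer concentration ratios of tracer and target are equal;
* the **improved** method, which first constructs the concentration *expected*
  from dilution alone,

  ``Ce2e = (Ce1 - Ca1) / (Ci1 - Ca1) * (Ci2 - Ca2) + Ca2``,

  and then adjusts via ``Ce2** = Ce2 * Ci2 / Ce2e``, valid for any combination
  of injection and aquifer concentrations.

Symbols follow field convention: ``Ci`` injection-fluid concentration, ``Ca``
aquifer (background) concentration, ``Ce`` extracted-fluid concentration;
subscript 1 marks the nonreactive tracer, 2 the (potentially) reactive target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import numpy.typing as npt

__all__ = [
    "PushPullError",
    "DegenerateTracerError",
    "SoluteSpec",
    "TestDesign",
    "BreakthroughSeries",
    "AdjustedSeries",
    "AssumptionReport",
    "conventional_adjust",
    "expected_concentration",
    "improved_adjust",
    "relative_breakthrough",
    "dilution_fraction",
    "check_ratio_assumption",
]

Role = Literal["nonreactive", "reactive"]
Method = Literal["conventional", "improved"]


class PushPullError(ValueError):
    """Domain error in push-pull test data or configuration."""


class DegenerateTracerError(PushPullError):
    """Tracer injection and aquifer concentrations coincide; the dilution
    fraction denominator (Ci1 - Ca1) is zero and no adjustment is defined."""


def _as_float_array(x: Sequence[float] | npt.ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise PushPullError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SoluteSpec:
    """One solute's role and its injection- and aquifer-fluid concentrations.

    Parameters
    ----------
    name
        Label used to key the solute in designs and series (e.g. ``"bromide"``).
    role
        ``"nonreactive"`` for a conservative tracer candidate, else ``"reactive"``.
    c_injection
        Concentration in the injection fluid (Ci), >= 0.
    c_aquifer
        Background concentration in the aquifer fluid (Ca), >= 0.
    units
        Free-text concentration units carried as a label; never converted.
    """

    name: str
    role: Role
    c_injection: float
    c_aquifer: float
    units: str = "mg/L"

    def __post_init__(self) -> None:
        if self.role not in ("nonreactive", "reactive"):
            raise PushPullError(f"solute {self.name!r}: unknown role {self.role!r}")
        if not np.isfinite(self.c_injection) or self.c_injection < 0:
            raise PushPullError(
                f"solute {self.name!r}: c_injection must be finite and >= 0, "
                f"got {self.c_injection}"
            )
        if not np.isfinite(self.c_aquifer) or self.c_aquifer < 0:
            raise PushPullError(
                f"solute {self.name!r}: c_aquifer must be finite and >= 0, "
                f"got {self.c_aquifer}"
            )

    @property
    def injection_aquifer_ratio(self) -> Optional[float]:
        """Ci/Ca, or None when the aquifer concentration is zero."""
        if self.c_aquifer == 0:
            return None
        return self.c_injection / self.c_aquifer


@dataclass(frozen=True)
class TestDesign:
    """The set of solutes in a push-pull test plus the optional injection volume.

    At least one solute must be nonreactive (the dilution-tracer candidate).
    ``injected_mass(name)`` returns Mi = Ci * Vi when a volume is given.
    """

    solutes: Dict[str, SoluteSpec]
    v_injection: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.solutes:
            raise PushPullError("design must contain at least one solute")
        for key, spec in self.solutes.items():
            if key != spec.name:
                raise PushPullError(
                    f"design key {key!r} does not match solute name {spec.name!r}"
                )
        if not any(s.role == "nonreactive" for s in self.solutes.values()):
            raise PushPullError("design must contain at least one nonreactive solute")
        if self.v_injection is not None and not self.v_injection > 0:
            raise PushPullError(f"v_injection must be > 0, got {self.v_injection}")

    @classmethod
    def from_solutes(
        cls, solutes: Sequence[SoluteSpec], v_injection: Optional[float] = None
    ) -> "TestDesign":
        names = [s.name for s in solutes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PushPullError(f"duplicate solute names in design: {dupes}")
        return cls({s.name: s for s in solutes}, v_injection)

    def solute(self, name: str) -> SoluteSpec:
        try:
            return self.solutes[name]
        except KeyError:
            raise PushPullError(
                f"unknown solute {name!r}; design has {sorted(self.solutes)}"
            ) from None

    def tracer(self, name: str) -> SoluteSpec:
        """Look up *name* and require it to be a nonreactive tracer with a
        nondegenerate dilution signal (Ci != Ca)."""
        spec = self.solute(name)
        if spec.role != "nonreactive":
            raise PushPullError(
                f"tracer {name!r} has role {spec.role!r}; the dilution tracer "
                "must be nonreactive"
            )
        return spec

    def injected_mass(self, name: str) -> float:
        if self.v_injection is None:
            raise PushPullError(
                "injected mass requires v_injection in the design"
            )
        return self.solute(name).c_injection * self.v_injection


@dataclass(frozen=True)
class BreakthroughSeries:
    """Time-stamped extracted-fluid concentrations for one pull phase.

    ``time`` is elapsed time since the start of the pull phase (the push phase
    is assumed to end immediately before; any drift phase is neglected).  All
    solutes share the one time grid.  ``volume`` optionally carries the
    cumulative extracted volume aligned with ``time``.
    """

    time: np.ndarray
    concentrations: Dict[str, np.ndarray]
    volume: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        object.__setattr__(self, "time", t)
        if t.size == 0:
            raise PushPullError("series must contain at least one sample")
        if t[0] < 0:
            raise PushPullError(f"time must start at >= 0, got {t[0]}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise PushPullError(
                f"time must be strictly increasing; sample {k} (t={t[k]}) "
                f"does not follow t={t[k - 1]}"
            )
        if not self.concentrations:
            raise PushPullError("series must contain at least one solute")
        conc = {}
        for name, values in self.concentrations.items():
            c = _as_float_array(values, f"concentrations[{name!r}]")
            if c.size != t.size:
                raise PushPullError(
                    f"solute {name!r} has {c.size} samples but time has {t.size}"
                )
            if np.any(~np.isfinite(c)) or np.any(c < 0):
                k = int(np.flatnonzero(~np.isfinite(c) | (c < 0))[0])
                raise PushPullError(
                    f"solute {name!r}: concentration at sample {k} "
                    f"(t={t[k]}) is negative or non-finite: {c[k]}"
                )
            conc[name] = c
        object.__setattr__(self, "concentrations", conc)
        if self.volume is not None:
            v = _as_float_array(self.volume, "volume")
            if v.size != t.size:
                raise PushPullError(
                    f"volume has {v.size} samples but time has {t.size}"
                )
            if v.size > 1 and np.any(np.diff(v) < 0):
                k = int(np.flatnonzero(np.diff(v) < 0)[0]) + 1
                raise PushPullError(
                    f"cumulative volume must be nondecreasing; sample {k} "
                    f"(v={v[k]}) < previous (v={v[k - 1]})"
                )
            object.__setattr__(self, "volume", v)

    def __len__(self) -> int:
        return self.time.size

    @property
    def solute_names(self) -> list[str]:
        return list(self.concentrations)

    def concentration(self, name: str) -> np.ndarray:
        try:
            return self.concentrations[name]
        except KeyError:
            raise PushPullError(
                f"solute {name!r} not in series; have {sorted(self.concentrations)}"
            ) from None


@dataclass(frozen=True)
class AdjustedSeries:
    """Dilution-adjusted (and, for the improved method, expected) breakthrough
    curve of one target solute.

    ``adjusted`` is Ce2* for the conventional method and Ce2** for the improved
    method; ``expected`` carries Ce2e and is None for the conventional method.
    Injection/aquifer concentrations are copied from the design for downstream
    fitting and reporting.
    """

    solute: str
    method: Method
    time: np.ndarray
    adjusted: np.ndarray
    expected: Optional[np.ndarray] = None
    c_injection: float = field(default=np.nan)
    c_aquifer: float = field(default=np.nan)
    units: str = "mg/L"

    def __post_init__(self) -> None:
        if self.method not in ("conventional", "improved"):
            raise PushPullError(f"unknown adjustment method {self.method!r}")
        t = _as_float_array(self.time, "time")
        a = _as_float_array(self.adjusted, "adjusted")
        if a.size != t.size:
            raise PushPullError("adjusted and time must be the same length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "adjusted", a)
        if self.expected is not None:
            e = _as_float_array(self.expected, "expected")
            if e.size != t.size:
                raise PushPullError("expected and time must be the same length")
            object.__setattr__(self, "expected", e)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class AssumptionReport:
    """Diagnostic for the equal-ratio assumption behind the conventional method.

    The conventional adjustment is exact only when Ci1/Ca1 = Ci2/Ca2.  The
    report carries both ratios, their relative difference (scaled by the larger
    ratio), and a verdict at the stated tolerance.  When either aquifer
    concentration is zero the ratio is undefined and the verdict is False with
    a reason; this is advisory — both methods stay computable regardless.
    """

    tracer: str
    target: str
    tracer_ratio: Optional[float]
    target_ratio: Optional[float]
    relative_difference: Optional[float]
    holds: bool
    tolerance: float
    reason: Optional[str] = None


def conventional_adjust(
    series: BreakthroughSeries, design: TestDesign, tracer: str, target: str
) -> AdjustedSeries:
    """Conventional dilution adjustment Ce2* = Ce2 * Ci1 / Ce1.

    The target concentration is multiplied by the inverse relative change of
    the tracer, so e.g. a twofold tracer dilution doubles the target.  Valid
    only under the equal-ratio assumption (see :func:`check_ratio_assumption`);
    when that fails the curve over- or under-adjusts — deliberately not masked
    here.

    Raises
    ------
    PushPullError
        If the tracer is not nonreactive, a solute is missing, or any tracer
        sample is <= 0 (the adjustment divides by Ce1).
    """
    tracer_spec = design.tracer(tracer)
    design.solute(target)
    ce1 = series.concentration(tracer)
    ce2 = series.concentration(target)
    bad = np.flatnonzero(ce1 <= 0)
    if bad.size:
        k = int(bad[0])
        raise PushPullError(
            f"conventional adjustment undefined: tracer {tracer!r} concentration "
            f"is {ce1[k]} at sample {k} (t={series.time[k]}); Ce1 must be > 0"
        )
    target_spec = design.solute(target)
    return AdjustedSeries(
        solute=target,
        method="conventional",
        time=series.time,
        adjusted=ce2 * tracer_spec.c_injection / ce1,
        expected=None,
        c_injection=target_spec.c_injection,
        c_aquifer=target_spec.c_aquifer,
        units=target_spec.units,
    )


def dilution_fraction(
    series: BreakthroughSeries, design: TestDesign, tracer: str
) -> np.ndarray:
    """Fraction of injection fluid remaining, (Ce1 - Ca1) / (Ci1 - Ca1).

    1 means no dilution (pure injection fluid, the t=0 state), 0 complete
    dilution (pure aquifer fluid, the long-time limit).  Values below 0 occur
    when the tracer overshoots below its aquifer background (measurement noise
    or a violated assumption); they are surfaced with a warning, not an error.
    """
    spec = design.tracer(tracer)
    denom = spec.c_injection - spec.c_aquifer
    if denom == 0:
        raise DegenerateTracerError(
            f"tracer {tracer!r} has c_injection == c_aquifer == {spec.c_injection}; "
            "dilution cannot be inferred from it"
        )
    frac = (series.concentration(tracer) - spec.c_aquifer) / denom
    if np.any(frac < 0):
        k = int(np.flatnonzero(frac < 0)[0])
        warnings.warn(
            f"tracer {tracer!r} overshoots its aquifer background at sample {k} "
            f"(t={series.time[k]}, dilution fraction {frac[k]:.4g})",
            stacklevel=2,
        )
    return frac


def expected_concentration(
    series: BreakthroughSeries, design: TestDesign, tracer: str, target: str
) -> np.ndarray:
    """Target concentration expected from dilution alone,
    Ce2e = (Ce1 - Ca1)/(Ci1 - Ca1) * (Ci2 - Ca2) + Ca2.

    An affine, order-preserving map of the tracer signal: it equals Ci2 when
    the tracer is undiluted and Ca2 when fully diluted, for any combination of
    injection and aquifer concentrations.  Deviation of the measured Ce2 from
    Ce2e is attributable to reaction (assuming identical transport behavior of
    tracer and target).
    """
    target_spec = design.solute(target)
    frac = dilution_fraction(series, design, tracer)
    return frac * (target_spec.c_injection - target_spec.c_aquifer) + target_spec.c_aquifer


def improved_adjust(
    series: BreakthroughSeries, design: TestDesign, tracer: str, target: str
) -> AdjustedSeries:
    """Improved dilution adjustment Ce2** = Ce2 * Ci2 / Ce2e.

    Uses the expected-from-dilution concentration as the reference, so the
    adjusted curve equals the injected concentration exactly when the target
    behaves as a diluted nonreactive solute — regardless of whether the
    equal-ratio assumption of the conventional method holds.

    Raises
    ------
    PushPullError
        If any expected concentration Ce2e is <= 0 (tracer overshoot below
        background, or Ci2 < Ca2 driving the affine map through zero); the
        adjustment is undefined there.
    """
    target_spec = design.solute(target)
    ce2e = expected_concentration(series, design, tracer, target)
    bad = np.flatnonzero(ce2e <= 0)
    if bad.size:
        k = int(bad[0])
        raise PushPullError(
            f"improved adjustment undefined: expected concentration of "
            f"{target!r} is {ce2e[k]:.4g} at sample {k} (t={series.time[k]}); "
            "Ce2e must be > 0"
        )
    ce2 = series.concentration(target)
    return AdjustedSeries(
        solute=target,
        method="improved",
        time=series.time,
        adjusted=ce2 * target_spec.c_injection / ce2e,
        expected=ce2e,
        c_injection=target_spec.c_injection,
        c_aquifer=target_spec.c_aquifer,
        units=target_spec.units,
    )


def relative_breakthrough(
    series: BreakthroughSeries, design: TestDesign, solute: str
) -> np.ndarray:
    """Breakthrough relative to the injected concentration, Ce/Ci."""
    spec = design.solute(solute)
    if spec.c_injection <= 0:
        raise PushPullError(
            f"relative breakthrough of {solute!r} undefined: c_injection = "
            f"{spec.c_injection}"
        )
    return series.concentration(solute) / spec.c_injection


def check_ratio_assumption(
    design: TestDesign, tracer: str, target: str, tolerance: float = 0.05
) -> AssumptionReport:
    """Check the equal-ratio assumption Ci1/Ca1 = Ci2/Ca2 of the conventional method.

    The relative difference is |r1 - r2| / max(r1, r2); ``holds`` is True when
    it does not exceed *tolerance* (default 5%).  Aquifer concentrations of
    zero make a ratio undefined: the report flags it and returns holds=False
    with a reason instead of raising.
    """
    if not 0 <= tolerance:
        raise PushPullError(f"tolerance must be >= 0, got {tolerance}")
    tracer_spec = design.tracer(tracer)
    target_spec = design.solute(target)
    r1 = tracer_spec.injection_aquifer_ratio
    r2 = target_spec.injection_aquifer_ratio
    if r1 is None or r2 is None:
        which = [n for n, r in ((tracer, r1), (target, r2)) if r is None]
        return AssumptionReport(
            tracer=tracer,
            target=target,
            tracer_ratio=r1,
            target_ratio=r2,
            relative_difference=None,
            holds=False,
            tolerance=tolerance,
            reason=f"aquifer concentration is zero for {which}; ratio undefined",
        )
    if r1 == r2:
        reldiff = 0.0
    else:
        reldiff = abs(r1 - r2) / max(r1, r2)
    return AssumptionReport(
        tracer=tracer,
        target=target,
        tracer_ratio=r1,
        target_ratio=r2,
        relative_difference=reldiff,
        holds=reldiff <= tolerance,
        tolerance=tolerance,
    )
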