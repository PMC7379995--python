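"""File formats and report generation.

Breakthrough series travel as tidy (long-format) CSV with columns
``time, solute, concentration`` and an optional ``volume`` column carrying the
cumulative extracted volume; a wide-format convenience converter is provided.
Test designs are YAML mappings listing per-solute role, injection and aquifer
concentrations, and units.  Reports are versioned JSON: one record per
target x method x kinetic model, carrying the rate fit, recovery numbers, and
the equal-ratio assumption diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import kinetics
from .model import (
    AdjustedSeries,
    AssumptionReport,
    BreakthroughSeries,
    PushPullError,
    SoluteSpec,
    TestDesign,
    check_ratio_assumption,
    conventional_adjust,
    improved_adjust,
)

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "wide_to_long",
    "read_design",
    "write_design",
    "read_adjusted_csv",
    "write_adjusted_csv",
    "build_report",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


def _FLOAT_FORMAT(x) -> str:
    # shortest round-trippable decimal form (write∘read = identity)
    return repr(float(x))

_SERIES_COLUMNS = ("time", "solute", "concentration")


def read_series_csv(path: Union[str, Path]) -> BreakthroughSeries:
    """Read a tidy breakthrough-curve CSV into a :class:`BreakthroughSeries`.

    Requires columns ``time, solute, concentration`` (optional ``volume``).
    Every solute must be sampled on the same strictly increasing time grid;
    ragged solutes are rejected.  Errors cite 1-based file rows (header = row 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise PushPullError(f"{path}: missing required column(s) {missing}")
    has_volume = "volume" in df.columns

    times: Optional[np.ndarray] = None
    volume: Optional[np.ndarray] = None
    conc: Dict[str, np.ndarray] = {}
    for solute, group in df.groupby("solute", sort=False):
        t = group["time"].to_numpy(dtype=float)
        rows = group.index.to_numpy() + 2  # 1-based file rows, after the header
        if t.size > 1:
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                raise PushPullError(
                    f"{path}: time not strictly increasing for solute {solute!r} "
                    f"at row {rows[bad[0] + 1]} (t={t[bad[0] + 1]})"
                )
        c = group["concentration"].to_numpy(dtype=float)
        neg = np.flatnonzero(~np.isfinite(c) | (c < 0))
        if neg.size:
            raise PushPullError(
                f"{path}: negative or non-finite concentration for solute "
                f"{solute!r} at row {rows[neg[0]]} ({c[neg[0]]})"
            )
        if times is None:
            times = t
        elif t.size != times.size or not np.array_equal(t, times):
            raise PushPullError(
                f"{path}: solute {solute!r} is sampled on a different time grid "
                "than the first solute; all solutes must share one grid"
            )
        conc[str(solute)] = c
        if has_volume:
            v = group["volume"].to_numpy(dtype=float)
            if volume is None:
                volume = v
            elif not np.allclose(v, volume, rtol=0, atol=0):
                raise PushPullError(
                    f"{path}: volume column disagrees across solutes "
                    f"(first mismatch for {solute!r})"
                )
    if times is None:
        raise PushPullError(f"{path}: no data rows")
    return BreakthroughSeries(time=times, concentrations=conc, volume=volume)


def write_series_csv(series: BreakthroughSeries, path: Union[str, Path]) -> None:
    """Write a series as tidy CSV; inverse of :func:`read_series_csv`."""
    frames = []
    for name, c in series.concentrations.items():
        frame = {"time": series.time, "solute": name, "concentration": c}
        if series.volume is not None:
            frame["volume"] = series.volume
        frames.append(pd.DataFrame(frame))
    # repr keeps the shortest round-trippable float form (write∘read = identity)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def wide_to_long(df: pd.DataFrame, time_column: str = "time") -> pd.DataFrame:
    """Convert a wide table (one column per solute) to the tidy layout."""
    if time_column not in df.columns:
        raise PushPullError(f"wide table lacks time column {time_column!r}")
    id_vars = [time_column] + (["volume"] if "volume" in df.columns else [])
    long = df.melt(
        id_vars=id_vars, var_name="solute", value_name="concentration"
    ).rename(columns={time_column: "time"})
    order = ["time", "solute", "concentration"] + (
        ["volume"] if "volume" in df.columns else []
    )
    return long[order]


_DESIGN_KEYS = {"solutes", "v_injection"}
_SOLUTE_KEYS = {"name", "role", "c_injection", "c_aquifer", "units"}


def _parse_solute(name: str, entry: dict) -> SoluteSpec:
    unknown = set(entry) - _SOLUTE_KEYS
    if unknown:
        raise PushPullError(f"solute {name!r}: unknown key(s) {sorted(unknown)}")
    for req in ("role", "c_injection", "c_aquifer"):
        if req not in entry:
            raise PushPullError(f"solute {name!r}: missing key {req!r}")
    return SoluteSpec(
        name=name,
        role=entry["role"],
        c_injection=float(entry["c_injection"]),
        c_aquifer=float(entry["c_aquifer"]),
        units=str(entry.get("units", "mg/L")),
    )


def read_design(path: Union[str, Path]) -> TestDesign:
    """Read a test design from a YAML document.

    ``solutes`` is either a mapping ``name -> {role, c_injection, c_aquifer,
    units}`` or a list of such entries each carrying ``name`` (the list form
    detects duplicate solutes).  ``v_injection`` is optional.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PushPullError(f"{path}: design must be a mapping")
    unknown = set(doc) - _DESIGN_KEYS
    if unknown:
        raise PushPullError(f"{path}: unknown key(s) {sorted(unknown)}")
    raw = doc.get("solutes")
    if not raw:
        raise PushPullError(f"{path}: design lists no solutes")
    solutes: List[SoluteSpec] = []
    if isinstance(raw, dict):
        for name, entry in raw.items():
            solutes.append(_parse_solute(str(name), dict(entry)))
    elif isinstance(raw, list):
        for entry in raw:
            entry = dict(entry)
            if "name" not in entry:
                raise PushPullError(f"{path}: list-form solute entry lacks 'name'")
            name = str(entry.pop("name"))
            solutes.append(_parse_solute(name, entry))
    else:
        raise PushPullError(f"{path}: 'solutes' must be a mapping or a list")
    v_injection = doc.get("v_injection")
    return TestDesign.from_solutes(
        solutes, None if v_injection is None else float(v_injection)
    )


def write_design(design: TestDesign, path: Union[str, Path]) -> None:
    """Write a design as YAML; inverse of :func:`read_design`."""
    doc: dict = {
        "solutes": {
            s.name: {
                "role": s.role,
                "c_injection": s.c_injection,
                "c_aquifer": s.c_aquifer,
                "units": s.units,
            }
            for s in design.solutes.values()
        }
    }
    if design.v_injection is not None:
        doc["v_injection"] = design.v_injection
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_adjusted_csv(
    adjusted: Sequence[AdjustedSeries], path: Union[str, Path]
) -> None:
    """Write one or more adjusted curves as tidy CSV (columns: time, solute,
    method, adjusted, expected)."""
    frames = []
    for adj in adjusted:
        frames.append(
            pd.DataFrame(
                {
                    "time": adj.time,
                    "solute": adj.solute,
                    "method": adj.method,
                    "adjusted": adj.adjusted,
                    "expected": adj.expected
                    if adj.expected is not None
                    else np.full(len(adj), np.nan),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_adjusted_csv(
    path: Union[str, Path], design: TestDesign
) -> List[AdjustedSeries]:
    """Read curves written by :func:`write_adjusted_csv`; the design supplies
    each solute's injection/aquifer concentrations."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time", "solute", "method", "adjusted") if c not in df.columns]
    if missing:
        raise PushPullError(f"{path}: missing required column(s) {missing}")
    out: List[AdjustedSeries] = []
    for (solute, method), group in df.groupby(["solute", "method"], sort=False):
        spec = design.solute(str(solute))
        expected = None
        if "expected" in group.columns and not group["expected"].isna().all():
            expected = group["expected"].to_numpy(dtype=float)
        out.append(
            AdjustedSeries(
                solute=str(solute),
                method=str(method),  # type: ignore[arg-type]
                time=group["time"].to_numpy(dtype=float),
                adjusted=group["adjusted"].to_numpy(dtype=float),
                expected=expected,
                c_injection=spec.c_injection,
                c_aquifer=spec.c_aquifer,
                units=spec.units,
            )
        )
    if not out:
        raise PushPullError(f"{path}: no data rows")
    return out


def _fit_record(adj: AdjustedSeries, model: str) -> dict:
    fit = (
        kinetics.fit_first_order(adj)
        if model == "first_order"
        else kinetics.fit_zero_order(adj)
    )
    return asdict(fit)


def build_report(
    design: TestDesign,
    series: BreakthroughSeries,
    tracer: str,
    targets: Iterable[str],
    methods: Sequence[str] = ("conventional", "improved"),
    models: Sequence[str] = ("first_order", "zero_order"),
    tolerance: float = 0.05,
    extraction_rate: Optional[float] = None,
) -> dict:
    """Run adjust + fit + recovery for every target x method x model.

    Recovery factors need extracted volumes: taken from the series if present,
    else derived from ``extraction_rate``; otherwise the recovery fields are
    null with an explanatory note.  The tracer itself is always included as a
    target (its self-adjustment is the method's internal control: a constant
    curve at Ci1, rate 0, RF 1).
    """
    adjusters = {"conventional": conventional_adjust, "improved": improved_adjust}
    for m in methods:
        if m not in adjusters:
            raise PushPullError(f"unknown method {m!r}")
    for model in models:
        if model not in ("first_order", "zero_order"):
            raise PushPullError(f"unknown kinetic model {model!r}")

    volume = series.volume
    volume_note = None
    if volume is None and extraction_rate is not None:
        volume = kinetics.volume_from_rate(series.time, extraction_rate)
        volume_note = f"volumes derived from constant extraction rate {extraction_rate}"
    elif volume is None:
        volume_note = "no extracted volumes available; recovery not computed"

    all_targets = list(dict.fromkeys([tracer, *targets]))
    records = []
    for target in all_targets:
        assumption = check_ratio_assumption(design, tracer, target, tolerance)
        for method in methods:
            adj = adjusters[method](series, design, tracer, target)
            recovery = None
            if volume is not None:
                recovery = asdict(kinetics.recovery_factor(adj, volume))
            for model in models:
                records.append(
                    {
                        "target": target,
                        "tracer": tracer,
                        "method": method,
                        "model": model,
                        "units": adj.units,
                        "fit": _fit_record(adj, model),
                        "recovery": recovery,
                        "assumption": asdict(assumption),
                    }
                )
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tracer": tracer,
        "targets": all_targets,
        "methods": list(methods),
        "models": list(models),
        "tolerance": tolerance,
        "volume_note": volume_note,
        "records": records,
    }


def write_report(report: dict, path: Union[str, Path]) -> None:
    """Write a report dict as deterministic (sorted, indented) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def summarize_report(report: dict) -> str:
    """Human-readable report summary, numbers at 4 significant figures."""
    lines = [
        f"push-pull report (schema v{report['schema_version']}): "
        f"tracer {report['tracer']}, targets {', '.join(report['targets'])}"
    ]
    if report.get("volume_note"):
        lines.append(f"note: {report['volume_note']}")
    for rec in report["records"]:
        fit = rec["fit"]
        rf = rec["recovery"]
        rf_txt = f", RF={rf['recovery_factor']:.4g}" if rf else ""
        ast = "" if rec["assumption"]["holds"] else " [ratio assumption fails]"
        lines.append(
            f"  {rec['target']:>10s} {rec['method']:>12s} {rec['model']:>11s}: "
            f"rate={fit['rate']:.4g} ±{fit['ci95_halfwidth']:.4g} "
            f"(p={fit['p_value']:.4g}, reported {fit['reported_rate']:.4g})"
            f"{rf_txt}{ast}"
        )
    return "\n".join(lines)
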