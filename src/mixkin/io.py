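"""CSV/YAML readers and writers for the package's data schemas.

Schemas (comma-separated, UTF-8, '.' decimal):

* storage:  ``index_name, temperature_C, day, value[, sd, units, direction]``
* design:   ``run_id, <component or component_pct columns>, <responses...>``
* rates:    ``index_name, temperature_C, order, k``
* goals:    YAML ``goals: [{response, kind, low, high, target, weight, importance}]``

Reports are written deterministically (stable ordering, fixed rounding:
k to 4 dp, R2 to 3 dp, half-life to 2 dp) so regeneration is byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .desirability import DesirabilityGoal
from .errors import ParseError
from .kinetics import StorageSeries
from .mixture import DesignTable, MixtureDesignSpec
from .temperature import RateByTemperature

__all__ = [
    "read_storage_csv",
    "write_storage_csv",
    "read_design_csv",
    "read_rates_csv",
    "read_goals_yaml",
    "write_report",
]

_STORAGE_REQUIRED = ["index_name", "temperature_C", "day", "value"]


def read_storage_csv(path) -> list[StorageSeries]:
    """Parse a long-format storage CSV into StorageSeries, validating invariants."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in _STORAGE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("temperature_C", "day", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric {col!r} at line {row}")
        df[col] = coerced
    dup = df.duplicated(subset=["index_name", "temperature_C", "day"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicate (index, temperature, day) at line {row}")
    series = []
    for (name, temp), grp in df.groupby(["index_name", "temperature_C"], sort=True):
        grp = grp.sort_values("day")
        series.append(StorageSeries(
            index_name=str(name), temperature=float(temp),
            days=tuple(grp["day"]), values=tuple(grp["value"]),
            units=str(grp["units"].iat[0]) if "units" in grp else "",
            direction=(str(grp["direction"].iat[0]) if "direction" in grp
                       else "decreasing"),
        ))
    return series


def write_storage_csv(series: Sequence[StorageSeries], path) -> None:
    """Inverse of :func:`read_storage_csv`; round-trip lossless."""
    rows = []
    for s in sorted(series, key=lambda s: (s.index_name, s.temperature)):
        for d, v in zip(s.days, s.values):
            rows.append({"index_name": s.index_name, "temperature_C": s.temperature,
                         "day": d, "value": v, "units": s.units,
                         "direction": s.direction})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design_csv(path, spec: MixtureDesignSpec) -> DesignTable:
    """Parse a mixture-design CSV (header row required)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    return DesignTable(df, spec)


def read_rates_csv(path, order: int | None = 0) -> dict[str, RateByTemperature]:
    """Parse a rate-constant CSV into per-index RateByTemperature."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("index_name", "temperature_C", "order", "k"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if order is not None:
        df = df[df["order"] == order]
    out = {}
    for name, grp in df.groupby("index_name", sort=True):
        grp = grp.sort_values("temperature_C")
        out[str(name)] = RateByTemperature(
            index_name=str(name),
            temperatures=tuple(grp["temperature_C"].astype(float)),
            k_values=tuple(grp["k"].astype(float)),
            order=int(grp["order"].iat[0]),
        )
    return out


def read_goals_yaml(path) -> list[DesirabilityGoal]:
    """Parse a YAML goal file into DesirabilityGoal objects."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "goals" not in raw:
        raise ParseError(f"{path}: expected a top-level 'goals' list")
    goals = []
    for g in raw["goals"]:
        goals.append(DesirabilityGoal(
            response_name=g["response"], goal_kind=g["kind"],
            low=float(g["low"]), high=float(g["high"]),
            target=float(g["target"]) if g.get("target") is not None else None,
            weight=float(g.get("weight", 1.0)),
            importance=int(g.get("importance", 1)),
        ))
    return goals


_ROUNDING = {"k": 4, "r2": 3, "t_half": 2}


def _round_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if not pd.api.types.is_numeric_dtype(out[c]):
            continue
        if c.startswith("k"):
            out[c] = out[c].round(_ROUNDING["k"])
        elif c.startswith("r2") or c.endswith("_r2"):
            out[c] = out[c].round(_ROUNDING["r2"])
        elif "half" in c:
            out[c] = out[c].round(_ROUNDING["t_half"])
    return out


def write_report(results: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a results table as CSV or aligned plain text, deterministically."""
    path = Path(path)
    if results.empty:
        warnings.warn(f"writing header-only report to {path}", stacklevel=2)
    out = _round_columns(results)
    sort_cols = [c for c in ("index_name", "temperature_C", "response") if c in out]
    if sort_cols:
        out = out.sort_values(sort_cols).reset_index(drop=True)
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "text":
        path.write_text(out.to_string(index=False) + "\n")
    else:
        raise ParseError(f"unknown report format {format!r}")
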