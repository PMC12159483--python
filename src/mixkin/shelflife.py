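"""Shelf-life prediction and stability reporting.

Combines a selected reaction order with the Arrhenius temperature model:
the rate constant is extrapolated to the storage temperature of interest
and the rate law inverted either to the half-change time (t1/2, the
headline shelf-life convention for this product) or to a caller-supplied
limit such as the log10 10^6 cfu/mL microbial guideline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DirectionError, DomainError, SizeError, ValidationError
from .kinetics import StorageSeries, half_life, select_order
from .temperature import (
    ArrheniusResults,
    BallModel,
    EyringModel,
    ArrheniusModel,
    RateByTemperature,
)

__all__ = [
    "MICROBIAL_LIMIT_LOG10CFU",
    "ShelfLifeEstimate",
    "shelf_life_to_limit",
    "shelf_life_at_temperature",
    "stability_report",
    "StabilityStudy",
]

#: log10 of the 10^6 cells/mL ready-to-eat microbiological guideline
MICROBIAL_LIMIT_LOG10CFU = 6.0


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Predicted shelf life for one index at one storage temperature."""

    index_name: str
    temperature: float           # deg C
    criterion: str               # "half_change" | "limit"
    shelf_life_days: float
    limit_value: float | None = None

    def __post_init__(self):
        if self.criterion not in ("half_change", "limit"):
            raise ValidationError("criterion must be 'half_change' or 'limit'")
        if self.criterion == "limit" and self.limit_value is None:
            raise ValidationError("limit criterion needs limit_value")
        if self.shelf_life_days <= 0:
            raise ValidationError("shelf life must be positive")


def shelf_life_to_limit(c0: float, limit: float, k: float, order: int,
                        direction: str = "decreasing") -> float:
    """Days until the index moves from c0 to the limit under the rate law."""
    if k <= 0:
        raise DomainError("k must be > 0")
    if direction == "decreasing" and limit >= c0:
        raise DirectionError(
            f"limit {limit} not below c0 {c0} for a decreasing index"
        )
    if direction == "increasing" and limit <= c0:
        raise DirectionError(
            f"limit {limit} not above c0 {c0} for an increasing index"
        )
    if order == 0:
        return abs(limit - c0) / k
    if order == 1:
        if c0 <= 0 or limit <= 0:
            raise DomainError("first-order inversion needs positive levels")
        return abs(math.log(limit / c0)) / k
    if order == 2:
        if c0 <= 0 or limit <= 0:
            raise DomainError("second-order inversion needs positive levels")
        return abs(1.0 / limit - 1.0 / c0) / k
    raise ValidationError("order must be 0, 1 or 2")


def shelf_life_at_temperature(arrhenius: ArrheniusResults, c0: float,
                              temperature_c: float, criterion: str = "half_change",
                              limit_value: float | None = None, order: int = 0,
                              direction: str = "decreasing") -> ShelfLifeEstimate:
    """Extrapolate k to a temperature with the Arrhenius fit, invert the rate law."""
    k = arrhenius.predict_k(temperature_c)
    if criterion == "half_change":
        days = half_life(c0, k, order)
    elif criterion == "limit":
        if limit_value is None:
            raise ValidationError("limit criterion needs limit_value")
        days = shelf_life_to_limit(c0, limit_value, k, order, direction)
    else:
        raise ValidationError("criterion must be 'half_change' or 'limit'")
    return ShelfLifeEstimate(
        index_name=arrhenius.index_name, temperature=temperature_c,
        criterion=criterion, shelf_life_days=days, limit_value=limit_value,
    )


class StabilityStudy:
    """Multi-index, multi-temperature kinetic stability analysis.

    Built from a collection of :class:`StorageSeries`; produces the per-index
    per-temperature rate table (all three orders, selected order, half-life)
    and per-index Arrhenius/Eyring/Ball temperature fits.
    """

    def __init__(self, series: Iterable[StorageSeries]):
        self.series = list(series)
        if not self.series:
            raise SizeError("need at least one storage series")
        self.by_index: dict[str, list[StorageSeries]] = {}
        for s in self.series:
            self.by_index.setdefault(s.index_name, []).append(s)

    def rate_table(self) -> pd.DataFrame:
        """One row per index x temperature with k/R2 for every order."""
        rows = []
        for name in sorted(self.by_index):
            for s in sorted(self.by_index[name], key=lambda s: s.temperature):
                sel = select_order(s)
                row = {"index_name": name, "temperature_C": s.temperature,
                       "selected_order": sel.best_order}
                for order in (0, 1, 2):
                    if order in sel.fits:
                        f = sel.fits[order]
                        row[f"k{order}"] = f.k
                        row[f"r2_{order}"] = f.r2
                    else:  # inapplicable transform: explicit gap, not dropped
                        row[f"k{order}"] = np.nan
                        row[f"r2_{order}"] = np.nan
                row["t_half"] = sel.best.half_life()
                rows.append(row)
        return pd.DataFrame(rows)

    def temperature_table(self, order: int | None = None) -> pd.DataFrame:
        """Per-index Arrhenius/Eyring/Ball parameters from the selected order."""
        rate_tab = self.rate_table()
        rows = []
        for name, grp in rate_tab.groupby("index_name", sort=True):
            if len(grp) < 2:
                continue
            use_order = int(grp["selected_order"].mode().iat[0]) if order is None else order
            ks = grp[f"k{use_order}"].to_numpy(float)
            temps = grp["temperature_C"].to_numpy(float)
            ok = np.isfinite(ks) & (ks > 0)
            if ok.sum() < 2:
                rows.append({"index_name": name, "order": use_order})
                continue
            rates = RateByTemperature(name, tuple(temps[ok]), tuple(ks[ok]),
                                      order=use_order)
            arr = ArrheniusModel(rates).fit()
            eyr = EyringModel(rates).fit()
            ball = BallModel(rates).fit()
            rows.append({
                "index_name": name, "order": use_order,
                "k_ref": arr.k_ref, "T_ref_C": arr.T_ref - 273.15,
                "Ea_J_mol": arr.Ea, "arrhenius_r2": arr.r2,
                "delta_H_J_mol": eyr.delta_H, "delta_S_J_molK": eyr.delta_S,
                "eyring_r2": eyr.r2,
                "D_ref_days": ball.D_ref, "Z_C": ball.Z, "ball_r2": ball.r2,
            })
        return pd.DataFrame(rows)

    def report(self) -> pd.DataFrame:
        """Stability report with deterministic ordering and rounding
        (k to 4 dp, R2 to 3 dp, t1/2 to 2 dp)."""
        tab = self.rate_table()
        out = tab.copy()
        for c in out.columns:
            if c.startswith("k"):
                out[c] = out[c].round(4)
            elif c.startswith("r2"):
                out[c] = out[c].round(3)
        out["t_half"] = out["t_half"].round(2)
        return out.sort_values(["index_name", "temperature_C"]).reset_index(drop=True)

    def limiting_index(self, temperature_c: float | None = None) -> tuple[str, float]:
        """Index with the shortest half-life (the headline shelf life)."""
        tab = self.rate_table()
        if temperature_c is not None:
            tab = tab[tab["temperature_C"] == temperature_c]
        if tab.empty:
            raise SizeError("no series at the requested temperature")
        row = tab.loc[tab["t_half"].idxmin()]
        return str(row["index_name"]), float(row["t_half"])


def stability_report(series: Sequence[StorageSeries]) -> pd.DataFrame:
    """Functional wrapper: per index x temperature kinetic stability table."""
    return StabilityStudy(series).report()
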