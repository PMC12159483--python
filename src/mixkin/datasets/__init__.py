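"""Packaged fixtures: the lassi formulation and storage study tables.

All real data consumed by the worked examples live here as small CSVs:
the 17-run D-optimal mixture design with its 16 measured responses, the
published special-cubic coefficient table with fit statistics, the
6-index x 3-temperature x 6-day storage series, the published rate
constants/half-lives, the optimum formulation with predicted and observed
responses, and the day-0 levels used for half-life arithmetic.
``load_fixtures()`` loads everything and verifies integrity spot checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from ..errors import ValidationError
from ..kinetics import StorageSeries
from ..mixture import DesignTable, MixtureDesignSpec, ScheffeModel, scheffe_term_labels
from ..temperature import RateByTemperature

__all__ = [
    "lassi_spec",
    "load_design",
    "load_scheffe_models",
    "load_fit_stats",
    "load_storage",
    "load_rates",
    "load_optimum",
    "load_initial_levels",
    "load_metadata",
    "optimum_amounts",
    "FixtureSet",
    "load_fixtures",
]


def _read_csv(name: str, **kw) -> pd.DataFrame:
    ref = resources.files(__package__) / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kw)


def lassi_spec() -> MixtureDesignSpec:
    """The study's bounded 3-component mixture region (amounts in %)."""
    return MixtureDesignSpec(
        components=("juice", "dahi", "water"),
        lower_bounds=(5.0, 60.0, 15.0),
        upper_bounds=(9.5, 64.5, 19.5),
        total=84.5,
    )


def load_design() -> DesignTable:
    """17-run design with all 16 measured responses."""
    return DesignTable(_read_csv("design_runs.csv"), lassi_spec())


def load_scheffe_models() -> dict[str, ScheffeModel]:
    """Published special-cubic models, one per response, in pseudo coding."""
    df = _read_csv("scheffe_coefficients.csv")
    labels = scheffe_term_labels("special_cubic")
    models = {}
    for resp, grp in df.groupby("response", sort=False):
        coefs = grp.set_index("term")["coefficient"]
        models[resp] = ScheffeModel(
            degree="special_cubic",
            terms=tuple(labels),
            coefficients=tuple(float(coefs[t]) for t in labels),
            response_name=str(resp),
        )
    return models


def load_fit_stats() -> pd.DataFrame:
    """Published per-response fit statistics (mean, SD, CV%, R2 family)."""
    return _read_csv("scheffe_fit_stats.csv", index_col="response")


def load_storage() -> list[StorageSeries]:
    """Storage trajectories: 6 indices x 3 temperatures x 6 sampling days."""
    df = _read_csv("storage_series.csv")
    series = []
    for (name, temp), grp in df.groupby(["index_name", "temperature_C"], sort=False):
        grp = grp.sort_values("day")
        series.append(StorageSeries(
            index_name=str(name), temperature=float(temp),
            days=tuple(grp["day"].astype(float)),
            values=tuple(grp["value"].astype(float)),
            units=str(grp["units"].iat[0]),
            direction=str(grp["direction"].iat[0]),
        ))
    return series


def load_rates(order: int | None = 0) -> dict[str, RateByTemperature]:
    """Published rate constants by index (default: zero-order)."""
    df = _read_csv("rate_constants.csv")
    if order is not None:
        df = df[df["order"] == order]
    out = {}
    for name, grp in df.groupby("index_name", sort=False):
        grp = grp.sort_values("temperature_C")
        out[str(name)] = RateByTemperature(
            index_name=str(name),
            temperatures=tuple(grp["temperature_C"].astype(float)),
            k_values=tuple(grp["k"].astype(float)),
            order=int(grp["order"].iat[0]),
        )
    return out


def load_rate_table() -> pd.DataFrame:
    """Full published rate table (all orders, R2, printed half-lives)."""
    return _read_csv("rate_constants.csv")


def load_optimum() -> pd.DataFrame:
    """Predicted and observed responses at the optimum formulation."""
    return _read_csv("optimum.csv", index_col="response")


def load_initial_levels() -> dict[str, float]:
    """Day-0 levels of the stored quality indices (for half-life arithmetic)."""
    df = _read_csv("initial_levels.csv")
    return dict(zip(df["index_name"], df["c0"].astype(float)))


def load_metadata() -> dict:
    ref = resources.files(__package__) / "data" / "metadata.yaml"
    with resources.as_file(ref) as path:
        return yaml.safe_load(path.read_text())


def optimum_amounts() -> dict[str, float]:
    """Optimum formulation amounts (%) in spec component order."""
    meta = load_metadata()
    return {k: float(v) for k, v in meta["optimum"]["amounts_pct"].items()}


@dataclass
class FixtureSet:
    """Everything the worked examples need, loaded and spot-checked."""

    design: DesignTable
    scheffe_models: dict[str, ScheffeModel]
    fit_stats: pd.DataFrame
    storage: list[StorageSeries]
    rates: dict[str, RateByTemperature]
    rate_table: pd.DataFrame
    optimum: pd.DataFrame
    initial_levels: dict[str, float]
    metadata: dict


def load_fixtures() -> FixtureSet:
    """Load all fixture groups and verify integrity spot checks."""
    fx = FixtureSet(
        design=load_design(),
        scheffe_models=load_scheffe_models(),
        fit_stats=load_fit_stats(),
        storage=load_storage(),
        rates=load_rates(order=0),
        rate_table=load_rate_table(),
        optimum=load_optimum(),
        initial_levels=load_initial_levels(),
        metadata=load_metadata(),
    )
    checks = [
        (float(fx.design.data["total_flavonoid"].iloc[0]), 23.43,
         "design run 1 total flavonoid"),
        (fx.scheffe_models["total_flavonoid"].coefficients[0], 23.43,
         "TFC A coefficient"),
        (next(s for s in fx.storage
              if s.index_name == "tba" and s.temperature == 5).values[0],
         0.022, "day-0 TBA at 5C"),
        (fx.rates["total_plate_count"].k_values[0], 0.1646,
         "plate-count k at 5C"),
        (float(fx.optimum.loc["total_flavonoid", "predicted"]), 22.489,
         "optimum TFC prediction"),
        (optimum_amounts()["juice"], 9.189, "optimum juice %"),
    ]
    for got, want, what in checks:
        if abs(got - want) > 1e-9:
            raise ValidationError(
                f"fixture integrity check failed: {what} = {got}, expected {want}"
            )
    return fx
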