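"""Synthetic storage trajectories and mixture studies with known truth.

The generators emulate the two experimental designs the package analyses:

* multi-temperature storage: a quality index following an exact zero-,
  first- or second-order rate law whose rate constant obeys an Arrhenius
  law across temperatures, sampled on the study grid (days 0..15 every 3,
  at 5/15/25 degC, 3 replicates) with additive i.i.d. Gaussian noise on the
  concentration scale (per-day SDs in the real data are roughly constant);
  a lognormal option is available for multiplicative noise.
* bounded-simplex mixture designs: responses generated from a known Scheffé
  polynomial at each run's pseudo-component point plus Gaussian noise.

``recovery_experiment`` runs repeated simulate-fit cycles and reports bias,
RMSE and quantiles for the recovered parameters plus order-selection
accuracy — the self-consistency loop behind the package's stochastic tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import StorageSeries, fit_order, select_order
from .mixture import (
    DesignTable,
    MixtureDesignSpec,
    ScheffeModel,
    n_terms,
    scheffe_term_labels,
    to_pseudo,
)
from .temperature import ArrheniusModel, RateByTemperature, R_GAS

__all__ = [
    "StorageSimConfig",
    "MixtureSimConfig",
    "SimulatedStorage",
    "simulate_storage",
    "simulate_mixture_study",
    "recovery_experiment",
]

_KELVIN = 273.15


@dataclass(frozen=True)
class StorageSimConfig:
    """Ground truth for a multi-temperature storage simulation."""

    order: int = 0
    c0: float = 3.07                      # day-0 level (study's plate count)
    k_ref: float = 0.2011                 # per-day at T_ref
    Ea: float = 1.6e4                     # J/mol
    T_ref: float = 15.0                   # deg C
    temperatures: tuple[float, ...] = (5.0, 15.0, 25.0)
    days: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)
    replicates: int = 3
    noise_sd: float = 0.05                # index units
    direction: str = "increasing"
    noise: str = "gaussian"               # or "lognormal"
    index_name: str = "synthetic_index"
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.c0 <= 0:
            raise ValidationError("c0 must be > 0")
        if self.order not in (0, 1, 2):
            raise ValidationError("order must be 0, 1 or 2")
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError("direction must be 'increasing' or 'decreasing'")
        if self.noise not in ("gaussian", "lognormal"):
            raise ValidationError("noise must be 'gaussian' or 'lognormal'")

    def k_at(self, temperature_c: float) -> float:
        """True Arrhenius rate constant at a storage temperature."""
        T = temperature_c + _KELVIN
        Tref = self.T_ref + _KELVIN
        return self.k_ref * np.exp(-(self.Ea / R_GAS) * (1.0 / T - 1.0 / Tref))

    def trajectory(self, temperature_c: float, days=None) -> np.ndarray:
        """Exact noise-free trajectory of the configured rate law."""
        t = np.asarray(self.days if days is None else days, float)
        k = self.k_at(temperature_c)
        sign = 1.0 if self.direction == "increasing" else -1.0
        if self.order == 0:
            return self.c0 + sign * k * t
        if self.order == 1:
            return self.c0 * np.exp(sign * k * t)
        inv = 1.0 / self.c0 - sign * k * t
        if np.any(inv <= 0):
            warnings.warn(
                "second-order trajectory crosses zero; truncating", stacklevel=2
            )
            inv = np.maximum(inv, 1e-9)
        return 1.0 / inv


@dataclass
class SimulatedStorage:
    """Replicate means as StorageSeries plus the raw replicate table."""

    series: list[StorageSeries]
    replicates: pd.DataFrame
    config: StorageSimConfig


def simulate_storage(config: StorageSimConfig,
                     seed: int | None = None) -> SimulatedStorage:
    """Generate noisy storage trajectories; reproducible per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    series = []
    for T in config.temperatures:
        mean_traj = config.trajectory(T)
        reps = np.empty((config.replicates, mean_traj.size))
        for r in range(config.replicates):
            if config.noise == "gaussian":
                noisy = mean_traj + rng.normal(0.0, config.noise_sd, mean_traj.size)
            else:
                # multiplicative: median preserved, sd parameter on log scale
                noisy = mean_traj * rng.lognormal(0.0, config.noise_sd, mean_traj.size)
            if config.order in (1, 2) and np.any(noisy <= 0):
                warnings.warn("noise pushed values <= 0; truncating", stacklevel=2)
                noisy = np.maximum(noisy, 1e-9)
            reps[r] = noisy
            for d, v in zip(config.days, noisy):
                rows.append({"index_name": config.index_name, "temperature_C": T,
                             "replicate": r, "day": d, "value": v})
        series.append(StorageSeries(
            index_name=config.index_name, temperature=T,
            days=tuple(config.days), values=tuple(reps.mean(axis=0)),
            direction=config.direction,
        ))
    return SimulatedStorage(series=series, replicates=pd.DataFrame(rows),
                            config=config)


@dataclass(frozen=True)
class MixtureSimConfig:
    """Ground truth for a mixture-design simulation."""

    spec: MixtureDesignSpec
    true_coefficients: dict[str, tuple[float, ...]]
    design: tuple[tuple[float, ...], ...]     # actual amounts per run
    degree: str = "special_cubic"
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        p = n_terms(self.degree, self.spec.n_components)
        for name, coefs in self.true_coefficients.items():
            if len(coefs) != p:
                raise ValidationError(
                    f"response {name!r}: {len(coefs)} coefficients, "
                    f"{self.degree} needs {p}"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for run in self.design:
            if len(run) != self.spec.n_components:
                raise ValidationError("design run does not match spec components")


def simulate_mixture_study(config: MixtureSimConfig,
                           seed: int | None = None) -> DesignTable:
    """Responses = Scheffé polynomial at each run + Gaussian noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    amounts = np.asarray(config.design, float)
    labels = scheffe_term_labels(config.degree, config.spec.components)
    df = pd.DataFrame(amounts, columns=list(config.spec.components))
    df.insert(0, "run_id", np.arange(1, len(df) + 1))
    from .mixture import predict_response  # local import avoids cycle at module load

    for name, coefs in config.true_coefficients.items():
        model = ScheffeModel(config.degree, tuple(labels), tuple(coefs),
                             response_name=name)
        mean = np.array([
            predict_response(model, to_pseudo(a, config.spec)) for a in amounts
        ])
        df[name] = mean + rng.normal(0.0, config.noise_sd, mean.size)
    return DesignTable(df, config.spec)


def recovery_experiment(config, n_replicates: int = 200,
                        seed: int | None = None) -> pd.DataFrame:
    """Repeated simulate-fit cycles; parameter-recovery summary table.

    For a :class:`StorageSimConfig`: recovery of k at each temperature and
    of the Arrhenius Ea, plus order-selection accuracy.  For a
    :class:`MixtureSimConfig`: recovery of every Scheffé coefficient.
    """
    rng = np.random.default_rng(seed)
    if isinstance(config, StorageSimConfig):
        return _storage_recovery(config, n_replicates, rng)
    if isinstance(config, MixtureSimConfig):
        return _mixture_recovery(config, n_replicates, rng)
    raise ValidationError("config must be StorageSimConfig or MixtureSimConfig")


def _summary_row(name: str, truth: float, estimates: np.ndarray) -> dict:
    err = estimates - truth
    rel = np.abs(err) / abs(truth) if truth != 0 else np.abs(err)
    return {
        "parameter": name, "truth": truth,
        "mean_estimate": float(estimates.mean()),
        "bias": float(err.mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "median_abs_rel_error": float(np.median(rel)),
        "q05": float(np.quantile(estimates, 0.05)),
        "q95": float(np.quantile(estimates, 0.95)),
    }


def _storage_recovery(config: StorageSimConfig, n_replicates: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    k_hat = {T: [] for T in config.temperatures}
    ea_hat = []
    order_correct = 0
    for _ in range(n_replicates):
        sim = simulate_storage(config, seed=int(rng.integers(2**31 - 1)))
        ks = []
        for s in sim.series:
            fit = fit_order(s, config.order)
            k_hat[s.temperature].append(fit.k)
            ks.append(fit.k)
            if select_order(s).best_order == config.order:
                order_correct += 1
        if all(k > 0 for k in ks):
            rates = RateByTemperature(config.index_name,
                                      tuple(config.temperatures), tuple(ks),
                                      order=config.order)
            ea_hat.append(ArrheniusModel(rates, t_ref=config.T_ref).fit().Ea)
    rows = [
        _summary_row(f"k@{T:g}C", config.k_at(T), np.asarray(k_hat[T]))
        for T in config.temperatures
    ]
    rows.append(_summary_row("Ea", config.Ea, np.asarray(ea_hat)))
    out = pd.DataFrame(rows)
    out.attrs["order_selection_accuracy"] = order_correct / (
        n_replicates * len(config.temperatures)
    )
    return out


def _mixture_recovery(config: MixtureSimConfig, n_replicates: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    from .mixture import ScheffeMixture

    labels = scheffe_term_labels(config.degree, config.spec.components)
    est: dict[tuple[str, str], list[float]] = {
        (resp, t): [] for resp in config.true_coefficients for t in labels
    }
    rmse_hat: dict[str, list[float]] = {r: [] for r in config.true_coefficients}
    for _ in range(n_replicates):
        table = simulate_mixture_study(config, seed=int(rng.integers(2**31 - 1)))
        for resp in config.true_coefficients:
            res = ScheffeMixture(table, resp, degree=config.degree).fit()
            for t, b in res.params.items():
                est[(resp, t)].append(float(b))
            rmse_hat[resp].append(res.stats.root_mse)
    rows = []
    for resp, coefs in config.true_coefficients.items():
        for t, truth in zip(labels, coefs):
            r = _summary_row(f"{resp}:{t}", truth, np.asarray(est[(resp, t)]))
            rows.append(r)
        rows.append(_summary_row(f"{resp}:root_mse", config.noise_sd,
                                 np.asarray(rmse_hat[resp])))
    return pd.DataFrame(rows)
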