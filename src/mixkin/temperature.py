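"""Temperature dependence of degradation rate constants.

Three classical models, all fitted as straight lines by ordinary least
squares:

* Arrhenius (reference-temperature form):
  ``ln k = ln k_ref - (Ea/R) (1/T - 1/T_ref)`` with T in kelvin and T_ref
  defaulting to the arithmetic mean of the input temperatures.  The slope
  of ln k on (1/T - 1/T_ref) gives the activation energy Ea = -slope * R.
* Eyring (transition-state):
  ``ln(k/T) = -(dH/R)(1/T) + ln(kB/h) + dS/R``; the intercept decomposes
  into the activation entropy via the Boltzmann/Planck constant ratio.
  k is converted from per-day to per-second first so the kB/h intercept is
  dimensionally meaningful; dH is unit-invariant, dS is not.
* Ball (thermal-death-time): ``log10(D/D_ref) = -(T - T_ref)/Z`` with
  D = ln(10)/k the decimal-reduction time and T in degrees Celsius.

Each ``*Model(rates).fit()`` returns a results object with the parameters,
R2 and prediction methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SingularityError, SizeError, ValidationError

__all__ = [
    "R_GAS",
    "BOLTZMANN",
    "PLANCK",
    "SECONDS_PER_DAY",
    "RateByTemperature",
    "ArrheniusModel",
    "ArrheniusResults",
    "EyringModel",
    "EyringResults",
    "BallModel",
    "BallResults",
    "fit_arrhenius",
    "fit_eyring",
    "fit_ball",
    "d_value",
]

R_GAS = 8.314            # J/(mol K)
BOLTZMANN = 1.381e-23    # J/K
PLANCK = 6.626e-34       # J s
SECONDS_PER_DAY = 86_400.0
_KELVIN = 273.15


@dataclass(frozen=True)
class RateByTemperature:
    """Rate-constant magnitudes for one quality index across temperatures."""

    index_name: str
    temperatures: tuple[float, ...]  # degrees C
    k_values: tuple[float, ...]      # per-day magnitudes
    order: int = 0

    def __post_init__(self):
        if len(self.temperatures) != len(self.k_values):
            raise ValidationError("temperatures and k values must pair up")
        if len(self.temperatures) < 2:
            raise SizeError("need rate constants at >= 2 temperatures")
        if len(set(self.temperatures)) < 2:
            raise SingularityError("zero temperature spread")
        if any(k <= 0 for k in self.k_values):
            raise DomainError("all rate constants must be > 0")

    @property
    def kelvin(self) -> np.ndarray:
        return np.asarray(self.temperatures, float) + _KELVIN

    @property
    def mean_temperature(self) -> float:
        """Arithmetic mean of the input temperatures (deg C), the default T_ref."""
        return float(np.mean(self.temperatures))


def _ols(x: np.ndarray, y: np.ndarray):
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise SingularityError("no spread in regressor")
    slope = float(((x - xbar) * (y - ybar)).sum()) / sxx
    intercept = ybar - slope * xbar
    yhat = intercept + slope * x
    sstot = float(((y - ybar) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - sse / sstot if sstot > 0 else (1.0 if sse < 1e-30 else 0.0)
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# Arrhenius


@dataclass
class ArrheniusResults:
    """Arrhenius fit: rate at the reference temperature and activation energy."""

    index_name: str
    k_ref: float      # per-day, at T_ref
    Ea: float         # J/mol
    T_ref: float      # K
    r2: float

    def predict_k(self, temperature_c: float) -> float:
        """Rate constant (per day) at a storage temperature in deg C."""
        if np.any(np.asarray(temperature_c) <= -_KELVIN):
            raise DomainError("temperature below absolute zero")
        T = np.asarray(temperature_c, float) + _KELVIN
        k = self.k_ref * np.exp(-(self.Ea / R_GAS) * (1.0 / T - 1.0 / self.T_ref))
        return float(k) if np.isscalar(temperature_c) else k

    def summary(self) -> str:
        return (
            f"Arrhenius [{self.index_name}]: k_ref={self.k_ref:.4f}/d at "
            f"T_ref={self.T_ref - _KELVIN:.2f} C, Ea={self.Ea / 1000:.3f} kJ/mol, "
            f"R2={self.r2:.3f}"
        )


class ArrheniusModel:
    """ln k regressed on (1/T - 1/T_ref), T in kelvin."""

    def __init__(self, rates: RateByTemperature, t_ref: float | None = None):
        self.rates = rates
        self.t_ref_c = rates.mean_temperature if t_ref is None else float(t_ref)

    def fit(self) -> ArrheniusResults:
        T = self.rates.kelvin
        Tref = self.t_ref_c + _KELVIN
        x = 1.0 / T - 1.0 / Tref
        y = np.log(np.asarray(self.rates.k_values, float))
        slope, intercept, r2 = _ols(x, y)
        return ArrheniusResults(
            index_name=self.rates.index_name,
            k_ref=math.exp(intercept),
            Ea=-slope * R_GAS,
            T_ref=Tref,
            r2=r2,
        )


def fit_arrhenius(rates: RateByTemperature, t_ref: float | None = None) -> ArrheniusResults:
    return ArrheniusModel(rates, t_ref=t_ref).fit()


# ---------------------------------------------------------------------------
# Eyring


@dataclass
class EyringResults:
    """Eyring fit: activation enthalpy and entropy (k handled in s^-1)."""

    index_name: str
    delta_H: float    # J/mol
    delta_S: float    # J/(mol K)
    r2: float
    k_units: str = "1/s"

    def summary(self) -> str:
        return (
            f"Eyring [{self.index_name}]: dH={self.delta_H / 1000:.3f} kJ/mol, "
            f"dS={self.delta_S:.2f} J/(mol K), R2={self.r2:.3f}"
        )


class EyringModel:
    """ln(k/T) regressed on 1/T; intercept = ln(kB/h) + dS/R."""

    def __init__(self, rates: RateByTemperature):
        self.rates = rates

    def fit(self) -> EyringResults:
        T = self.rates.kelvin
        k_per_s = np.asarray(self.rates.k_values, float) / SECONDS_PER_DAY
        y = np.log(k_per_s / T)
        x = 1.0 / T
        slope, intercept, r2 = _ols(x, y)
        ln_kb_h = math.log(BOLTZMANN / PLANCK)
        return EyringResults(
            index_name=self.rates.index_name,
            delta_H=-slope * R_GAS,
            delta_S=R_GAS * (intercept - ln_kb_h),
            r2=r2,
        )


def fit_eyring(rates: RateByTemperature) -> EyringResults:
    return EyringModel(rates).fit()


# ---------------------------------------------------------------------------
# Ball


def d_value(k: float) -> float:
    """Decimal-reduction time D = ln(10)/k (days for a per-day k)."""
    if k <= 0:
        raise DomainError("D-value needs k > 0")
    return math.log(10.0) / k


@dataclass
class BallResults:
    """Ball fit: D at the reference temperature and the Z-value."""

    index_name: str
    D_ref: float      # days
    Z: float          # deg C for a tenfold D change; inf if the line is flat
    T_ref: float      # deg C
    r2: float

    def predict_d(self, temperature_c: float) -> float:
        if math.isinf(self.Z):
            return self.D_ref
        return float(self.D_ref * 10.0 ** (-(temperature_c - self.T_ref) / self.Z))

    def summary(self) -> str:
        z = "inf" if math.isinf(self.Z) else f"{self.Z:.2f}"
        return (
            f"Ball [{self.index_name}]: D_ref={self.D_ref:.2f} d at "
            f"T_ref={self.T_ref:.2f} C, Z={z} C, R2={self.r2:.3f}"
        )


class BallModel:
    """log10 D regressed on (T - T_ref) in deg C; Z = -1/slope."""

    def __init__(self, rates: RateByTemperature, t_ref: float | None = None):
        self.rates = rates
        self.t_ref_c = rates.mean_temperature if t_ref is None else float(t_ref)

    def fit(self) -> BallResults:
        T = np.asarray(self.rates.temperatures, float)
        D = np.array([d_value(k) for k in self.rates.k_values])
        x = T - self.t_ref_c
        y = np.log10(D)
        slope, intercept, r2 = _ols(x, y)
        Z = float("inf") if slope == 0 else -1.0 / slope
        return BallResults(
            index_name=self.rates.index_name,
            D_ref=10.0 ** intercept,
            Z=Z,
            T_ref=self.t_ref_c,
            r2=r2,
        )


def fit_ball(rates: RateByTemperature, t_ref: float | None = None) -> BallResults:
    return BallModel(rates, t_ref=t_ref).fit()
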