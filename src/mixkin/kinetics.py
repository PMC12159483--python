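"""Zero-, first- and second-order degradation kinetics for storage series.

A quality index C(t) sampled over storage days is fitted by ordinary least
squares on the linearizing transform of each reaction order:

    order 0:  C       = C0 - k t
    order 1:  ln C    = ln C0 - k t
    order 2:  1/C     = 1/C0 + k t

For indices that increase during storage (acidity, free fatty acids, TBA,
microbial counts) the slope has the opposite sign; k is stored as a
magnitude together with the direction of change, matching how rate tables
in the food-stability literature print it.  Model choice is by the
coefficient of determination on the transformed scale, with ties broken
toward the lower order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, SizeError, ValidationError

__all__ = [
    "StorageSeries",
    "KineticResults",
    "DegradationKinetics",
    "OrderSelection",
    "fit_order",
    "select_order",
    "chi_square",
    "half_life",
]

ORDERS = (0, 1, 2)


@dataclass(frozen=True)
class StorageSeries:
    """One quality index at one storage temperature over sampling days."""

    index_name: str
    temperature: float  # degrees C
    days: tuple[float, ...]
    values: tuple[float, ...]
    units: str = ""
    direction: str = "decreasing"

    def __post_init__(self):
        d = np.asarray(self.days, float)
        if d.size < 3:
            raise SizeError("a storage series needs at least 3 time points")
        if d[0] != 0:
            raise ValidationError("sampling days must start at 0")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("sampling days must be strictly increasing")
        if len(self.values) != d.size:
            raise ValidationError("days and values must have equal length")
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError("direction must be 'increasing' or 'decreasing'")

    @property
    def c0_observed(self) -> float:
        """Observed day-0 level (half-life uses this, not the fitted intercept)."""
        return float(self.values[0])


def _ols_line(t: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression; returns slope, intercept, r2."""
    tbar, ybar = t.mean(), y.mean()
    stt = float(((t - tbar) ** 2).sum())
    slope = float(((t - tbar) * (y - ybar)).sum()) / stt
    intercept = ybar - slope * tbar
    yhat = intercept + slope * t
    sse = float(((y - yhat) ** 2).sum())
    sstot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - sse / sstot if sstot > 0 else (1.0 if sse == 0 else 0.0)
    return slope, intercept, r2


@dataclass
class KineticResults:
    """Fitted rate law for one series at one order."""

    series: StorageSeries
    order: int
    k: float            # rate-constant magnitude
    c0_fit: float       # back-transformed intercept
    r2: float
    chi_square: float
    direction: str      # sign of change implied by the fitted slope
    slope: float        # raw slope on the transformed scale
    intercept: float

    def predict(self, t) -> np.ndarray:
        """Concentration-scale prediction at times ``t`` (days)."""
        t = np.asarray(t, float)
        z = self.intercept + self.slope * t
        if self.order == 0:
            return z
        if self.order == 1:
            return np.exp(z)
        return 1.0 / z

    def half_life(self, c0: float | None = None) -> float:
        """Time for the index to change by half its initial level (days)."""
        c0 = self.series.c0_observed if c0 is None else c0
        return half_life(c0, self.k, self.order)

    def summary(self) -> str:
        return (
            f"{self.series.index_name} @ {self.series.temperature:g} C, "
            f"order {self.order}: k={self.k:.4f}, C0_fit={self.c0_fit:.4f}, "
            f"R2={self.r2:.3f}, chi2={self.chi_square:.3g}, "
            f"t1/2={self.half_life():.2f} d"
        )


class DegradationKinetics:
    """Kinetic model of one storage series at a fixed reaction order."""

    def __init__(self, series: StorageSeries, order: int):
        if order not in ORDERS:
            raise ValidationError(f"order must be one of {ORDERS}")
        self.series = series
        self.order = order
        vals = np.asarray(series.values, float)
        if order in (1, 2) and np.any(vals <= 0):
            raise DomainError(
                f"order {order} transform needs strictly positive values"
            )

    def fit(self) -> KineticResults:
        s = self.series
        t = np.asarray(s.days, float)
        c = np.asarray(s.values, float)
        if self.order == 0:
            y = c
        elif self.order == 1:
            y = np.log(c)
        else:
            y = 1.0 / c
        slope, intercept, r2 = _ols_line(t, y)
        k = abs(slope)
        # direction of change on the concentration scale implied by the slope
        if self.order == 2:
            direction = "decreasing" if slope > 0 else "increasing"
        else:
            direction = "decreasing" if slope < 0 else "increasing"
        if self.order == 0:
            c0_fit = intercept
        elif self.order == 1:
            c0_fit = math.exp(intercept)
        else:
            c0_fit = 1.0 / intercept if intercept != 0 else float("inf")
        res = KineticResults(
            series=s, order=self.order, k=k, c0_fit=c0_fit, r2=r2,
            chi_square=0.0, direction=direction, slope=slope, intercept=intercept,
        )
        res.chi_square = chi_square(res, s)
        return res


def fit_order(series: StorageSeries, order: int) -> KineticResults:
    """Fit one reaction order to a series (functional wrapper)."""
    return DegradationKinetics(series, order).fit()


def chi_square(fit: KineticResults, series: StorageSeries) -> float:
    """Reduced chi-square sum((O-P)^2)/(n-p) on the concentration scale."""
    t = np.asarray(series.days, float)
    obs = np.asarray(series.values, float)
    n, p = t.size, 2
    if n <= p:
        raise SizeError("chi-square undefined for n <= number of parameters")
    pred = fit.predict(t)
    return float(((obs - pred) ** 2).sum() / (n - p))


@dataclass
class OrderSelection:
    """All candidate fits for a series plus the selected best order."""

    best_order: int
    fits: dict[int, KineticResults]
    skipped: dict[int, str] = field(default_factory=dict)

    @property
    def best(self) -> KineticResults:
        return self.fits[self.best_order]


def select_order(series: StorageSeries) -> OrderSelection:
    """Fit all applicable orders; pick highest R2, ties toward lower order."""
    fits: dict[int, KineticResults] = {}
    skipped: dict[int, str] = {}
    for order in ORDERS:
        try:
            fits[order] = fit_order(series, order)
        except DomainError as exc:
            skipped[order] = str(exc)
    if not fits:
        raise DomainError(f"no reaction order applicable to {series.index_name}")
    best = max(sorted(fits), key=lambda o: (fits[o].r2, -o))
    return OrderSelection(best_order=best, fits=fits, skipped=skipped)


def half_life(c0: float, k: float, order: int) -> float:
    """t1/2: time for the index to change by half its initial level.

    order 0: c0/(2k); order 1: ln2/k; order 2: 1/(k c0).  For increasing
    indices the same formulas give the time to change by c0/2.
    """
    if c0 <= 0:
        raise DomainError("half-life needs c0 > 0")
    if k < 0:
        raise DomainError("k must be a non-negative magnitude")
    if k == 0:
        return float("inf")
    if order == 0:
        return c0 / (2.0 * k)
    if order == 1:
        return math.log(2.0) / k
    if order == 2:
        return 1.0 / (k * c0)
    raise ValidationError(f"order must be one of {ORDERS}")
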