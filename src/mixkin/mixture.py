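"""Scheffé mixture polynomials on a bounded simplex.

A q-component mixture with a fixed total and per-component bounds is mapped
onto the unit simplex via L-pseudo-component coding,

    a_i = (x_i - L_i) / (total - sum(L)),

and modelled with intercept-free Scheffé polynomials.  The special cubic
degree, used throughout the lassi formulation study this package ships as a
worked example, has seven terms for three components:

    y = b_A a + b_B b + b_C c + b_AB ab + b_AC ac + b_BC bc + b_ABC abc.

The model/results split follows the statsmodels convention:
:class:`ScheffeMixture` holds the data and design, ``fit()`` returns a
:class:`ScheffeResults` carrying coefficients, response-surface ANOVA
statistics and prediction methods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    ConfigurationError,
    ModelError,
    SingularityError,
    SizeError,
    ValidationError,
)

__all__ = [
    "MixtureDesignSpec",
    "DesignTable",
    "ScheffeModel",
    "FitStats",
    "ScheffeMixture",
    "ScheffeResults",
    "to_pseudo",
    "from_pseudo",
    "scheffe_terms",
    "scheffe_term_labels",
    "predict_response",
    "d_optimal_select",
]

DEGREES = ("linear", "quadratic", "special_cubic")

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class MixtureDesignSpec:
    """Bounded mixture region: component names, % bounds and the fixed total."""

    components: tuple[str, ...]
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]
    total: float

    def __post_init__(self):
        q = len(self.components)
        if not (len(self.lower_bounds) == len(self.upper_bounds) == q):
            raise ValidationError("components and bounds must have equal length")
        if self.total <= 0:
            raise ValidationError("mixture total must be positive")
        if any(lo < 0 for lo in self.lower_bounds):
            raise ValidationError("lower bounds must be non-negative")
        if any(hi < lo for lo, hi in zip(self.lower_bounds, self.upper_bounds)):
            raise ValidationError("upper bound below lower bound")
        if not (sum(self.lower_bounds) < self.total < sum(self.upper_bounds)):
            raise ValidationError(
                "need sum(lower) < total < sum(upper) for a non-degenerate region"
            )

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def pseudo_scale(self) -> float:
        """Denominator of the L-pseudo coding, total - sum(lower)."""
        return self.total - sum(self.lower_bounds)


def to_pseudo(actual: Sequence[float], spec: MixtureDesignSpec) -> np.ndarray:
    """Map actual amounts (%) to L-pseudo-component proportions.

    Raises :class:`BoundsError` naming the offending component if an amount
    falls below its lower bound or the amounts do not add up to the fixed
    mixture total.
    """
    x = np.asarray(actual, dtype=float)
    if x.shape != (spec.n_components,):
        raise ValidationError(
            f"expected {spec.n_components} amounts, got {x.shape}"
        )
    if abs(x.sum() - spec.total) > _SUM_TOL * max(1.0, spec.total):
        raise BoundsError(
            f"amounts sum to {x.sum():.6f}, not the fixed total {spec.total}"
        )
    for name, xi, lo in zip(spec.components, x, spec.lower_bounds):
        if xi < lo - _SUM_TOL:
            raise BoundsError(f"component {name!r}: amount {xi} below lower bound {lo}")
    p = (x - np.asarray(spec.lower_bounds)) / spec.pseudo_scale
    return p


def from_pseudo(pseudo: Sequence[float], spec: MixtureDesignSpec) -> np.ndarray:
    """Inverse of :func:`to_pseudo`; validates that proportions sum to 1."""
    p = np.asarray(pseudo, dtype=float)
    if p.shape != (spec.n_components,):
        raise ValidationError(
            f"expected {spec.n_components} proportions, got {p.shape}"
        )
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValidationError("pseudo proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"pseudo proportions sum to {p.sum()}, not 1")
    return p * spec.pseudo_scale + np.asarray(spec.lower_bounds)


def scheffe_term_labels(degree: str, components: Sequence[str] | None = None) -> list[str]:
    """Ordered term labels (A, B, ..., AB, AC, ..., ABC) for a Scheffé degree."""
    if degree not in DEGREES:
        raise ConfigurationError(f"unknown degree {degree!r}; use one of {DEGREES}")
    q = 3 if components is None else len(components)
    letters = [chr(ord("A") + i) for i in range(q)]
    labels = list(letters)
    if degree in ("quadratic", "special_cubic"):
        labels += ["".join(c) for c in itertools.combinations(letters, 2)]
    if degree == "special_cubic":
        labels += ["".join(c) for c in itertools.combinations(letters, 3)]
    return labels


def scheffe_terms(pseudo: Sequence[float], degree: str) -> np.ndarray:
    """Evaluate the Scheffé model terms at one pseudo-component point."""
    if degree not in DEGREES:
        raise ConfigurationError(f"unknown degree {degree!r}; use one of {DEGREES}")
    p = np.asarray(pseudo, dtype=float)
    q = p.size
    vals = list(p)
    if degree in ("quadratic", "special_cubic"):
        vals += [p[i] * p[j] for i, j in itertools.combinations(range(q), 2)]
    if degree == "special_cubic":
        vals += [p[i] * p[j] * p[k] for i, j, k in itertools.combinations(range(q), 3)]
    return np.array(vals)


def n_terms(degree: str, q: int = 3) -> int:
    return len(scheffe_term_labels(degree, ["?"] * q))


@dataclass
class DesignTable:
    """Mixture design: per-run actual component amounts plus measured responses.

    ``data`` holds one row per run with the component columns named after
    ``spec.components`` (a ``<name>_pct`` suffix is also accepted on input)
    and any number of response columns.
    """

    data: pd.DataFrame
    spec: MixtureDesignSpec
    run_id_column: str = "run_id"

    def __post_init__(self):
        df = self.data.copy()
        # accept "<comp>_pct" aliases from the CSV schema
        renames = {
            f"{c}_pct": c for c in self.spec.components if f"{c}_pct" in df.columns
        }
        df = df.rename(columns=renames)
        missing = [c for c in self.spec.components if c not in df.columns]
        if missing:
            raise ValidationError(f"design table missing component columns {missing}")
        amounts = df[list(self.spec.components)].to_numpy(float)
        sums = amounts.sum(axis=1)
        bad = np.abs(sums - self.spec.total) > _SUM_TOL * max(1.0, self.spec.total)
        if bad.any():
            i = int(np.argmax(bad))
            raise BoundsError(
                f"run {df.index[i]}: amounts sum to {sums[i]:.6f}, "
                f"not {self.spec.total}"
            )
        lo = np.asarray(self.spec.lower_bounds)
        hi = np.asarray(self.spec.upper_bounds)
        if (amounts < lo - _SUM_TOL).any() or (amounts > hi + _SUM_TOL).any():
            raise BoundsError("a run violates the component bounds")
        self.data = df

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def response_names(self) -> list[str]:
        skip = set(self.spec.components) | {self.run_id_column}
        return [c for c in self.data.columns if c not in skip]

    def amounts(self) -> np.ndarray:
        return self.data[list(self.spec.components)].to_numpy(float)

    def pseudo(self) -> np.ndarray:
        """All runs mapped to pseudo-component proportions, shape (n, q)."""
        return np.vstack([to_pseudo(row, self.spec) for row in self.amounts()])

    def response(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ValidationError(f"no response column {name!r}")
        return self.data[name].to_numpy(float)


@dataclass(frozen=True)
class ScheffeModel:
    """Fitted (or published) Scheffé polynomial for one response."""

    degree: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    response_name: str = ""
    response_units: str = ""

    def __post_init__(self):
        if len(self.terms) != len(self.coefficients):
            raise ModelError("one coefficient per term required")
        expected = len(scheffe_term_labels(self.degree))
        if len(self.terms) != expected:
            raise ModelError(
                f"{self.degree} model needs {expected} terms, got {len(self.terms)}"
            )


@dataclass
class FitStats:
    """Response-surface ANOVA summary for one fitted Scheffé model."""

    r2: float
    adjusted_r2: float | None
    predicted_r2: float | None
    cv_percent: float
    adequate_precision: float
    model_f: float
    grand_mean: float
    root_mse: float
    lack_of_fit_f: float | None = None
    pure_error_df: int = 0


def predict_response(model: ScheffeModel, pseudo: Sequence[float]) -> float:
    """Evaluate a Scheffé model at a pseudo-component point (dot product)."""
    t = scheffe_terms(pseudo, model.degree)
    if t.size != len(model.coefficients):
        raise ModelError(
            f"model has {len(model.coefficients)} terms but point yields {t.size}"
        )
    return float(t @ np.asarray(model.coefficients))


def _design_matrix(pseudo_points: np.ndarray, degree: str) -> np.ndarray:
    return np.vstack([scheffe_terms(p, degree) for p in pseudo_points])


class ScheffeMixture:
    """Scheffé mixture-polynomial model for one response of a design table.

    Parameters
    ----------
    design : DesignTable
        Runs with actual component amounts and measured responses.
    response : str
        Name of the response column to model.
    degree : {"linear", "quadratic", "special_cubic"}
        Scheffé polynomial degree (intercept-free).
    """

    def __init__(self, design: DesignTable, response: str,
                 degree: str = "special_cubic", response_units: str = ""):
        if degree not in DEGREES:
            raise ConfigurationError(f"unknown degree {degree!r}")
        self.design = design
        self.response_name = response
        self.degree = degree
        self.response_units = response_units
        self.endog = design.response(response)
        self.pseudo_points = design.pseudo()
        self.exog = _design_matrix(self.pseudo_points, degree)
        self.term_labels = scheffe_term_labels(degree, design.spec.components)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       spec: MixtureDesignSpec, **kw) -> "ScheffeMixture":
        return cls(DesignTable(data, spec), response, **kw)

    def fit(self) -> "ScheffeResults":
        X, y = self.exog, self.endog
        n, p = X.shape
        if n < p:
            raise SizeError(f"{n} runs cannot identify {p} model terms")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the collinear terms: those whose removal restores full rank
            collinear = []
            for j in range(p):
                Xj = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(Xj) == rank:
                    collinear.append(self.term_labels[j])
            raise SingularityError(
                f"design matrix rank {rank} < {p}; collinear terms: {collinear}"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        model = ScheffeModel(
            degree=self.degree,
            terms=tuple(self.term_labels),
            coefficients=tuple(beta),
            response_name=self.response_name,
            response_units=self.response_units,
        )
        return ScheffeResults(self, model)


class ScheffeResults:
    """Fit results: coefficients, diagnostics and prediction for one response."""

    def __init__(self, model_obj: ScheffeMixture, model: ScheffeModel):
        self.model_obj = model_obj
        self.model = model
        self.params = pd.Series(model.coefficients, index=list(model.terms),
                                name=model.response_name)
        X = model_obj.exog
        self.fittedvalues = X @ np.asarray(model.coefficients)
        self.resid = model_obj.endog - self.fittedvalues
        self.stats = self._fit_statistics()

    # -- statistics ---------------------------------------------------------
    def _fit_statistics(self) -> FitStats:
        X = self.model_obj.exog
        y = self.model_obj.endog
        n, p = X.shape
        yhat = self.fittedvalues
        e = self.resid
        sse = float(e @ e)
        ybar = float(y.mean())
        sstot = float(((y - ybar) ** 2).sum())  # mean-corrected: no-intercept Scheffé
        if sstot <= 1e-12 * max(1.0, ybar**2):
            warnings.warn(
                f"response {self.model.response_name!r} is constant; R^2 reported as 0",
                stacklevel=2,
            )
            r2 = 0.0
            adj = pred = None
        else:
            r2 = 1.0 - sse / sstot
            adj = None
            pred = None
            if n > p:
                adj = 1.0 - (sse / (n - p)) / (sstot / (n - 1))
                # PRESS via the hat-matrix leave-one-out identity
                H = X @ np.linalg.solve(X.T @ X, X.T)
                h = np.diag(H)
                with np.errstate(divide="ignore", invalid="ignore"):
                    press = float((((e) / (1.0 - h)) ** 2).sum())
                pred = 1.0 - press / sstot
            else:
                warnings.warn("n <= p: adjusted/predicted R^2 undefined", stacklevel=2)
        mse = sse / (n - p) if n > p else float("nan")
        rmse = float(np.sqrt(mse)) if n > p else float("nan")
        cv = 100.0 * rmse / ybar if ybar != 0 else float("nan")
        spread = float(yhat.max() - yhat.min())
        adeq = spread / np.sqrt(p * mse / n) if n > p and mse > 0 else float("inf")
        ssmodel = sstot - sse
        model_f = (ssmodel / (p - 1)) / mse if n > p and p > 1 and mse > 0 else float("inf")
        lof_f, pe_df = self._lack_of_fit(sse, n, p)
        return FitStats(
            r2=r2, adjusted_r2=adj, predicted_r2=pred, cv_percent=cv,
            adequate_precision=adeq, model_f=model_f, grand_mean=ybar,
            root_mse=rmse, lack_of_fit_f=lof_f, pure_error_df=pe_df,
        )

    def _lack_of_fit(self, sse: float, n: int, p: int):
        """Pure-error / lack-of-fit F decomposition over replicated runs."""
        pts = self.model_obj.pseudo_points
        y = self.model_obj.endog
        keys = [tuple(np.round(pt, 9)) for pt in pts]
        groups: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            groups.setdefault(k, []).append(i)
        ss_pe = 0.0
        df_pe = 0
        for idx in groups.values():
            if len(idx) > 1:
                yi = y[list(idx)]
                ss_pe += float(((yi - yi.mean()) ** 2).sum())
                df_pe += len(idx) - 1
        if df_pe == 0:
            return None, 0
        m = len(groups)
        df_lof = m - p
        if df_lof <= 0:
            return None, df_pe
        ss_lof = max(sse - ss_pe, 0.0)
        if ss_pe <= 0:
            return float("inf"), df_pe
        return (ss_lof / df_lof) / (ss_pe / df_pe), df_pe

    # -- prediction ---------------------------------------------------------
    def predict(self, pseudo=None, actual=None) -> float | np.ndarray:
        """Predict the response at pseudo proportions or actual amounts (%)."""
        if (pseudo is None) == (actual is None):
            raise ValidationError("give exactly one of pseudo= or actual=")
        if actual is not None:
            pseudo = to_pseudo(actual, self.model_obj.design.spec)
        pseudo = np.asarray(pseudo, dtype=float)
        if pseudo.ndim == 1:
            return predict_response(self.model, pseudo)
        return np.array([predict_response(self.model, p) for p in pseudo])

    def summary(self) -> str:
        s = self.stats
        lines = [
            f"Scheffe {self.model.degree} model: {self.model.response_name}",
            "=" * 58,
            "term        coefficient",
        ]
        for t, c in self.params.items():
            lines.append(f"{t:<10s}  {c: .4f}")
        lines += [
            "-" * 58,
            f"grand mean {s.grand_mean:.4f}   root MSE {s.root_mse:.4f}   "
            f"C.V.% {s.cv_percent:.2f}",
            f"R2 {s.r2:.4f}   adj R2 "
            + (f"{s.adjusted_r2:.4f}" if s.adjusted_r2 is not None else "n/a")
            + "   pred R2 "
            + (f"{s.predicted_r2:.4f}" if s.predicted_r2 is not None else "n/a"),
            f"adeq precision {s.adequate_precision:.2f}   model F {s.model_f:.2f}",
        ]
        if s.lack_of_fit_f is not None:
            lines.append(
                f"lack-of-fit F {s.lack_of_fit_f:.2f} (pure-error df {s.pure_error_df})"
            )
        return "\n".join(lines)


def fit_scheffe(design: DesignTable, response_name: str, degree: str = "special_cubic",
                spec: MixtureDesignSpec | None = None):
    """Functional wrapper: fit one response, return (ScheffeModel, FitStats)."""
    if spec is not None and spec is not design.spec:
        design = DesignTable(design.data, spec)
    res = ScheffeMixture(design, response_name, degree=degree).fit()
    return res.model, res.stats


def d_optimal_select(candidates: np.ndarray, n_runs: int, degree: str = "special_cubic",
                     seed: int | None = None, n_iter: int = 50) -> np.ndarray:
    """Greedy Fedorov-exchange D-optimal subset of candidate pseudo points.

    Returns the indices of the selected candidates.  det(X'X) is
    non-decreasing across exchange passes; ties break toward the first
    candidate index; an optional seed shuffles the initial greedy build.
    """
    cand = np.asarray(candidates, dtype=float)
    F = _design_matrix(cand, degree)
    m, p = F.shape
    if n_runs < p:
        raise SizeError(f"n_runs={n_runs} < {p} model terms")
    if n_runs > m:
        raise SizeError(f"n_runs={n_runs} exceeds {m} candidates")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m) if seed is not None else np.arange(m)

    # greedy build: add the point giving the largest det gain
    selected: list[int] = []
    for _ in range(n_runs):
        best_gain, best_idx = -np.inf, None
        Xs = F[selected] if selected else np.empty((0, p))
        M = Xs.T @ Xs + 1e-12 * np.eye(p)
        Minv = np.linalg.inv(M)
        for i in order:
            f = F[i]
            gain = float(f @ Minv @ f)
            if gain > best_gain + 1e-15:
                best_gain, best_idx = gain, int(i)
        selected.append(best_idx)
        order = order[order != best_idx]

    def logdet(idx):
        Xs = F[idx]
        sign, ld = np.linalg.slogdet(Xs.T @ Xs)
        return ld if sign > 0 else -np.inf

    current = logdet(selected)
    for _ in range(n_iter):
        improved = False
        for si, s in enumerate(list(selected)):
            best_ld, best_j = current, None
            for j in range(m):
                if j in selected:
                    continue
                trial = list(selected)
                trial[si] = j
                ld = logdet(trial)
                if ld > best_ld + 1e-12:
                    best_ld, best_j = ld, j
            if best_j is not None:
                selected[si] = best_j
                current = best_ld
                improved = True
        if not improved:
            break
    return np.array(sorted(selected))
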