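"""Derringer–Suich desirability scoring and formulation optimization.

Each response (or mixture component) is mapped to a desirability d in [0, 1]
by a one- or two-sided ramp; the overall desirability is the
importance-weighted geometric mean

    D = (prod d_i^r_i)^(1 / sum r_i),

which is 0 whenever any individual d_i is 0.  The optimizer searches the
constrained mixture simplex with a coarse grid followed by local refinement,
which is robust to the flat zero regions the ramps create.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FeasibilityError, ValidationError
from .mixture import MixtureDesignSpec, ScheffeModel, predict_response, to_pseudo

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability_score",
    "overall_desirability",
    "optimize_formulation",
    "FormulationOptimizer",
    "study_default_goals",
]

GOAL_KINDS = ("maximize", "minimize", "target", "in_range")


@dataclass(frozen=True)
class DesirabilityGoal:
    """One optimization goal for a response or a mixture component."""

    response_name: str
    goal_kind: str
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0
    importance: int = 1

    def __post_init__(self):
        if self.goal_kind not in GOAL_KINDS:
            raise ConfigurationError(
                f"unknown goal kind {self.goal_kind!r}; use one of {GOAL_KINDS}"
            )
        if not self.low < self.high:
            raise ValidationError("goal needs low < high")
        if self.weight <= 0:
            raise ValidationError("weight must be > 0")
        if self.importance < 1:
            raise ValidationError("importance must be >= 1")
        if self.goal_kind == "target":
            if self.target is None or not (self.low <= self.target <= self.high):
                raise ValidationError("target goal needs low <= target <= high")


def desirability_score(value: float, goal: DesirabilityGoal) -> float:
    """Derringer ramp desirability of one observed/predicted value."""
    v, lo, hi, w = value, goal.low, goal.high, goal.weight
    kind = goal.goal_kind
    if kind == "maximize":
        if v <= lo:
            return 0.0
        if v >= hi:
            return 1.0
        return ((v - lo) / (hi - lo)) ** w
    if kind == "minimize":
        if v >= hi:
            return 0.0
        if v <= lo:
            return 1.0
        return ((hi - v) / (hi - lo)) ** w
    if kind == "target":
        t = goal.target
        if v <= lo or v >= hi:
            # endpoints of a two-sided ramp score 0 except degenerate edges
            if v == t:
                return 1.0
            return 0.0
        if v == t:
            return 1.0
        if v < t:
            return ((v - lo) / (t - lo)) ** w
        return ((hi - v) / (hi - t)) ** w
    # in_range
    return 1.0 if lo <= v <= hi else 0.0


def overall_desirability(d_list: Sequence[float],
                         importance_list: Sequence[int] | None = None) -> float:
    """Importance-weighted geometric mean of individual desirabilities."""
    d = np.asarray(d_list, dtype=float)
    if d.size == 0:
        raise ValidationError("need at least one desirability")
    if np.any((d < 0) | (d > 1)):
        raise ValidationError("desirabilities must lie in [0, 1]")
    r = (np.ones_like(d) if importance_list is None
         else np.asarray(importance_list, dtype=float))
    if r.shape != d.shape:
        raise ValidationError("importance list length mismatch")
    if np.any(d == 0):
        return 0.0
    return float(np.exp((r * np.log(d)).sum() / r.sum()))


@dataclass
class OptimizationResult:
    """Best formulation found: amounts, predictions and desirabilities."""

    amounts: dict[str, float]
    pseudo: np.ndarray
    predictions: dict[str, float]
    desirabilities: dict[str, float]
    overall_desirability: float

    def summary(self) -> str:
        lines = ["Formulation optimum", "=" * 44]
        for name, v in self.amounts.items():
            lines.append(f"{name:<22s} {v:8.3f} %")
        lines.append("-" * 44)
        for name, v in self.predictions.items():
            d = self.desirabilities.get(name)
            tail = f"   d={d:.4f}" if d is not None else ""
            lines.append(f"{name:<22s} {v:8.3f}{tail}")
        lines.append("-" * 44)
        lines.append(f"overall desirability D = {self.overall_desirability:.4f}")
        return "\n".join(lines)


def study_default_goals(spec: MixtureDesignSpec,
                        response_spans: dict[str, tuple[float, float]] | None = None,
                        importance: int = 3) -> list[DesirabilityGoal]:
    """Default goal set for the lassi study: maximize the juice fraction,
    minimize dahi and water, keep responses within their observed spans.

    The study's own exact goal/weight table was not published, so this is a
    documented stand-in, not a reproduction.
    """
    names = spec.components
    goals = [
        DesirabilityGoal(names[0], "maximize", spec.lower_bounds[0],
                         spec.upper_bounds[0], importance=importance),
        DesirabilityGoal(names[1], "minimize", spec.lower_bounds[1],
                         spec.upper_bounds[1], importance=importance),
        DesirabilityGoal(names[2], "minimize", spec.lower_bounds[2],
                         spec.upper_bounds[2], importance=importance),
    ]
    for resp, (lo, hi) in (response_spans or {}).items():
        goals.append(DesirabilityGoal(resp, "in_range", lo, hi,
                                      importance=importance))
    return goals


class FormulationOptimizer:
    """Grid-then-refine maximizer of overall desirability on the simplex."""

    def __init__(self, models: Sequence[ScheffeModel], goals: Sequence[DesirabilityGoal],
                 spec: MixtureDesignSpec, grid_step: float = 0.5):
        self.models = {m.response_name: m for m in models}
        self.goals = list(goals)
        self.spec = spec
        self.grid_step = grid_step
        for g in self.goals:
            if (g.response_name not in self.models
                    and g.response_name not in spec.components):
                raise ValidationError(
                    f"goal {g.response_name!r} matches no model or component"
                )

    # -- objective ----------------------------------------------------------
    def _evaluate(self, amounts: np.ndarray):
        pseudo = to_pseudo(amounts, self.spec)
        preds = {name: predict_response(m, pseudo) for name, m in self.models.items()}
        comp = dict(zip(self.spec.components, amounts))
        ds, imps = {}, []
        for g in self.goals:
            v = comp[g.response_name] if g.response_name in comp else preds[g.response_name]
            ds[g.response_name] = desirability_score(v, g)
            imps.append(g.importance)
        D = overall_desirability([ds[g.response_name] for g in self.goals], imps)
        return pseudo, preds, ds, D

    def _feasible_grid(self):
        lo, hi = np.asarray(self.spec.lower_bounds), np.asarray(self.spec.upper_bounds)
        total = self.spec.total
        step = self.grid_step
        pts = []
        a_vals = np.arange(lo[0], hi[0] + 1e-9, step)
        b_vals = np.arange(lo[1], hi[1] + 1e-9, step)
        for a in a_vals:
            for b in b_vals:
                c = total - a - b
                if lo[2] - 1e-9 <= c <= hi[2] + 1e-9:
                    pts.append((a, b, min(max(c, lo[2]), hi[2])))
        if not pts:
            raise FeasibilityError("no feasible grid point in the mixture region")
        return np.asarray(pts)

    def optimize(self, seed: int | None = None, refine_step: float = 1e-3) -> OptimizationResult:
        """Best grid point, then shrinking local polytope search around it."""
        grid = self._feasible_grid()
        best_D, best_x = -1.0, None
        for x in grid:
            _, _, _, D = self._evaluate(x)
            if D > best_D + 1e-15:
                best_D, best_x = D, x
        if best_D <= 0.0:
            import warnings

            warnings.warn("desirability is 0 everywhere; returning best grid point",
                          stacklevel=2)
        # local refinement: coordinate exchanges within the polytope
        x = np.array(best_x, dtype=float)
        step = self.grid_step / 2.0
        lo, hi = np.asarray(self.spec.lower_bounds), np.asarray(self.spec.upper_bounds)
        while step >= refine_step:
            improved = False
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    trial = x.copy()
                    trial[i] += step
                    trial[j] -= step
                    if np.any(trial < lo - 1e-12) or np.any(trial > hi + 1e-12):
                        continue
                    trial = np.clip(trial, lo, hi)
                    if abs(trial.sum() - self.spec.total) > 1e-9:
                        continue
                    _, _, _, D = self._evaluate(trial)
                    if D > best_D + 1e-12:
                        best_D, x = D, trial
                        improved = True
            if not improved:
                step /= 2.0
        pseudo, preds, ds, D = self._evaluate(x)
        return OptimizationResult(
            amounts=dict(zip(self.spec.components, map(float, x))),
            pseudo=pseudo, predictions=preds, desirabilities=ds,
            overall_desirability=D,
        )


def optimize_formulation(models: Sequence[ScheffeModel], goals: Sequence[DesirabilityGoal],
                         spec: MixtureDesignSpec, seed: int | None = None,
                         grid_step: float = 0.5) -> OptimizationResult:
    """Functional wrapper around :class:`FormulationOptimizer`."""
    return FormulationOptimizer(models, goals, spec, grid_step=grid_step).optimize(seed=seed)
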