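"""Multi-response desirability optimization over fitted quadratic surfaces.

Each response gets a one-sided "larger is better" ramp: desirability 0 at or
below ``lower_bound``, 1 at or above ``target``, and a power ramp in between.
The composite is the geometric mean, maximized by a deterministic dense grid
scan with optional Nelder-Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .rsm import QuadraticModel

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimizationResult",
    "desirability_value",
    "composite_desirability",
    "optimize_desirability",
]


@dataclass(frozen=True)
class ResponseGoal:
    """One-sided maximize goal: d=0 at/below lower_bound, d=1 at/above target."""

    lower_bound: float
    target: float
    weight: float = 1.0
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if not self.lower_bound < self.target:
            raise ValueError("lower_bound must be < target")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")
        if self.direction != "maximize":
            raise ValueError("only direction='maximize' is supported")


@dataclass
class DesirabilitySpec:
    """Goals per response name; composite rule is the geometric mean."""

    goals: dict[str, ResponseGoal]


def desirability_value(y: float, goal: ResponseGoal) -> float:
    """Derringer-Suich one-sided ramp in [0, 1]."""
    if y <= goal.lower_bound:
        return 0.0
    if y >= goal.target:
        return 1.0
    return float(((y - goal.lower_bound) / (goal.target - goal.lower_bound)) ** goal.weight)


def composite_desirability(values) -> float:
    """Geometric mean of component desirabilities; 0 vetoes the composite."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("composite_desirability requires at least one value")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("component desirabilities must be in [0, 1]")
    if np.any(values == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


@dataclass
class OptimizationResult:
    best_point: np.ndarray
    predicted_responses: dict[str, float]
    composite_desirability: float
    search_trace: list[tuple[np.ndarray, float]] = field(default_factory=list)
    all_zero: bool = False


def _composite_at(
    x: np.ndarray, models: dict[str, QuadraticModel], spec: DesirabilitySpec
) -> float:
    d = [desirability_value(models[name].predict(x), spec.goals[name]) for name in spec.goals]
    return composite_desirability(d)


def optimize_desirability(
    models: dict[str, QuadraticModel],
    spec: DesirabilitySpec,
    bounds,
    grid_density: int = 51,
    refine: bool = True,
) -> OptimizationResult:
    """Maximize composite desirability of predicted responses over a box.

    ``bounds`` is a sequence of three (low, high) pairs.  A full grid of
    ``grid_density`` points per axis is scanned (ties broken by lexicographic
    grid order, axis 1 outermost); with ``refine`` the best cell seeds a
    Nelder-Mead polish whose result is kept only if it does not fall below
    the grid optimum.
    """
    for name in spec.goals:
        if name not in models:
            raise KeyError(f"no model for response {name!r}")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != 3 or any(not np.isfinite([lo, hi]).all() or hi < lo for lo, hi in bounds):
        raise ValueError("bounds must be three finite (low, high) pairs")

    axes = [np.linspace(lo, hi, grid_density) for lo, hi in bounds]
    G1, G2, G3 = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel(), G3.ravel()])

    # vectorized composite over the grid
    comp = np.ones(len(pts))
    for name, goal in spec.goals.items():
        pred = models[name].predict(pts)
        d = np.clip((pred - goal.lower_bound) / (goal.target - goal.lower_bound), 0.0, 1.0)
        comp *= d**goal.weight
    comp = comp ** (1.0 / len(spec.goals))

    best_idx = int(np.argmax(comp))  # first occurrence = lexicographic order
    best_x = pts[best_idx].copy()
    best_d = float(comp[best_idx])
    trace: list[tuple[np.ndarray, float]] = [(best_x.copy(), best_d)]

    if best_d == 0.0:
        return OptimizationResult(
            best_point=best_x,
            predicted_responses={n: float(models[n].predict(best_x)) for n in spec.goals},
            composite_desirability=0.0,
            search_trace=trace,
            all_zero=True,
        )

    if refine:
        def neg(x: np.ndarray) -> float:
            x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
            return -_composite_at(x, models, spec)

        res = optimize.minimize(
            neg, best_x, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10}
        )
        cand = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        cand_d = _composite_at(cand, models, spec)
        trace.append((cand.copy(), float(cand_d)))
        if cand_d >= best_d:
            best_x, best_d = cand, float(cand_d)

    return OptimizationResult(
        best_point=best_x,
        predicted_responses={n: float(models[n].predict(best_x)) for n in spec.goals},
        composite_desirability=best_d,
        search_trace=trace,
    )
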