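"""Bayesian-optimization loop over the formulation box.

Each iteration fits the GP surrogate to all data, proposes one point per
acquisition function (Expected Improvement and an upper Confidence Bound by
default, both computed from the same posterior), evaluates the experiment
callback on both, and appends the results.  The default schedule mirrors a
fixed budget of 6 iterations x 2 proposals from 8 initial runs; an
improvement-based early stop is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .gp import GPModel, fit_gp

__all__ = [
    "AcquisitionSpec",
    "BOIteration",
    "BOTrace",
    "expected_improvement",
    "confidence_bound",
    "propose_batch",
    "run_bo",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    kind: str  # "expected_improvement" or "confidence_bound"
    cb_kappa: float = 2.0
    maximize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("expected_improvement", "confidence_bound"):
            raise ValueError(f"unknown acquisition kind {self.kind!r}")
        if not np.isfinite(self.cb_kappa) or self.cb_kappa < 0:
            raise ValueError("cb_kappa must be finite and >= 0")


DEFAULT_BATCH = (AcquisitionSpec("expected_improvement"), AcquisitionSpec("confidence_bound"))


def expected_improvement(mean, sd, incumbent: float) -> np.ndarray | float:
    """EI for maximization: (mu - y*) Phi(z) + sigma phi(z); max(mu - y*, 0) at sd=0."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    improve = mean - incumbent
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, improve / np.where(sd > 0, sd, 1.0), 0.0)
        ei = np.where(
            sd > 0,
            improve * stats.norm.cdf(z) + sd * stats.norm.pdf(z),
            np.maximum(improve, 0.0),
        )
    out = np.maximum(ei, 0.0)
    return float(out) if out.ndim == 0 else out


def confidence_bound(mean, sd, kappa: float = 2.0) -> np.ndarray | float:
    """Upper confidence bound mu + kappa * sigma (maximization convention)."""
    out = np.asarray(mean, dtype=float) + kappa * np.asarray(sd, dtype=float)
    return float(out) if out.ndim == 0 else out


def _acquisition_values(model: GPModel, X: np.ndarray, acq: AcquisitionSpec, incumbent: float):
    mean, sd = model.posterior(X)
    if acq.kind == "expected_improvement":
        return expected_improvement(mean, sd, incumbent)
    return confidence_bound(mean, sd, acq.cb_kappa)


def propose_batch(
    model: GPModel,
    acqs: Sequence[AcquisitionSpec] = DEFAULT_BATCH,
    seed: int = 0,
    n_starts: int = 50,
) -> list[np.ndarray]:
    """One proposal per acquisition: seeded multistart + L-BFGS-B refinement.

    All proposals are computed from the same posterior (no fantasizing) and
    clipped to the model's input box.  Duplicate acquisition specs yield
    duplicate proposals.  A numerically flat acquisition falls back to the
    center of the box with a warning.
    """
    rng = np.random.default_rng(seed)
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    incumbent = float(model.y_raw.max())
    proposals = []
    # coarse grid shared by all acquisitions: cheap global pre-scan that the
    # local refinements start from, in addition to the seeded random starts
    axes = [np.linspace(l, h, 13) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(lo))
    for acq in acqs:
        starts = np.vstack([rng.uniform(lo, hi, size=(n_starts, len(lo))), grid])
        vals = np.asarray(_acquisition_values(model, starts, acq, incumbent))
        if np.ptp(vals) < 1e-15 and np.all(np.abs(vals - vals[0]) < 1e-15):
            warnings.warn(f"flat {acq.kind} acquisition; proposing the box center")
            proposals.append((lo + hi) / 2.0)
            continue

        def neg(x: np.ndarray) -> float:
            return -float(_acquisition_values(model, x[None, :], acq, incumbent)[0])

        order = np.argsort(vals)[::-1]
        best_x, best_v = starts[order[0]], vals[order[0]]
        for i in order[:5]:  # refine from the top starts only
            res = optimize.minimize(
                neg, starts[i], method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            if -res.fun > best_v:
                best_v, best_x = -res.fun, res.x
        proposals.append(np.clip(best_x, lo, hi))
    return proposals


@dataclass
class BOIteration:
    index: int
    proposals: list[np.ndarray]
    acquisition_kinds: list[str]
    acquisition_values: list[float]
    observed: list[float]
    incumbent_best: float


@dataclass
class BOTrace:
    init_X: np.ndarray
    init_y: np.ndarray
    iterations: list[BOIteration] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def all_X(self) -> np.ndarray:
        X = [self.init_X]
        for it in self.iterations:
            X.extend(p[None, :] for p in it.proposals)
        return np.vstack(X)

    @property
    def all_y(self) -> np.ndarray:
        y = list(self.init_y)
        for it in self.iterations:
            y.extend(it.observed)
        return np.array(y)

    @property
    def incumbent_best(self) -> float:
        return float(self.all_y.max())


def run_bo(
    oracle: Callable[[np.ndarray], float],
    init_X: np.ndarray,
    init_y: np.ndarray,
    bounds,
    n_iterations: int = 6,
    batch: Sequence[AcquisitionSpec] = DEFAULT_BATCH,
    seed: int = 0,
    restarts: int = 10,
    early_stop: bool = False,
    improvement_tol: float = 0.5,
) -> BOTrace:
    """Closed-loop BO: fit surrogate -> propose batch -> evaluate -> repeat.

    Runs exactly ``n_iterations`` iterations by default; with ``early_stop``
    the loop also halts once the incumbent improved by less than
    ``improvement_tol`` over the last two completed iterations.  Oracle
    failures truncate the trace with the exception recorded in stop_reason.
    """
    init_X = np.atleast_2d(np.asarray(init_X, dtype=float))
    init_y = np.asarray(init_y, dtype=float).ravel()
    bounds_arr = np.asarray([(float(lo), float(hi)) for lo, hi in bounds])
    if np.any(init_X < bounds_arr[:, 0]) or np.any(init_X > bounds_arr[:, 1]):
        raise ValueError("initial points must lie inside the bounds")
    trace = BOTrace(init_X=init_X, init_y=init_y)
    X, y = init_X, init_y
    incumbent_history = [float(y.max())]
    for it in range(1, n_iterations + 1):
        model = fit_gp(X, y, bounds_arr, restarts=restarts, seed=seed + 1000 * it)
        proposals = propose_batch(model, batch, seed=seed + 1000 * it)
        incumbent = float(y.max())
        acq_vals = [
            float(np.asarray(_acquisition_values(model, p[None, :], a, incumbent))[0])
            for p, a in zip(proposals, batch)
        ]
        observed = []
        try:
            for p in proposals:
                observed.append(float(oracle(p)))
        except Exception as exc:  # truncate on oracle failure
            trace.stop_reason = f"oracle failure: {exc}"
            if observed:
                trace.iterations.append(
                    BOIteration(
                        index=it,
                        proposals=proposals[: len(observed)],
                        acquisition_kinds=[a.kind for a in batch][: len(observed)],
                        acquisition_values=acq_vals[: len(observed)],
                        observed=observed,
                        incumbent_best=max(incumbent, max(observed)),
                    )
                )
            return trace
        X = np.vstack([X, np.vstack(proposals)])
        y = np.concatenate([y, observed])
        incumbent = float(y.max())
        trace.iterations.append(
            BOIteration(
                index=it,
                proposals=proposals,
                acquisition_kinds=[a.kind for a in batch],
                acquisition_values=acq_vals,
                observed=observed,
                incumbent_best=incumbent,
            )
        )
        incumbent_history.append(incumbent)
        if early_stop and len(incumbent_history) >= 3:
            if incumbent_history[-1] - incumbent_history[-3] < improvement_tol:
                trace.stop_reason = "converged"
                return trace
    trace.stop_reason = trace.stop_reason or "max_iterations"
    return trace
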