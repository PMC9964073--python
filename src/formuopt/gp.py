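"""Gaussian-process regression with an ARD Matern 3/2 kernel.

Inputs are scaled to the unit cube via the optimization box and outputs are
standardized internally; hyperparameters (signal variance and per-dimension
lengthscales on the scaled space) are chosen by marginal-likelihood
maximization with seeded multistart L-BFGS-B.  The posterior is exposed in
original response units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["GPHyperparams", "GPModel", "fit_gp", "matern32_kernel"]

_SQRT3 = np.sqrt(3.0)
# hard positivity bounds; fitting uses a tighter upper bound of twice the
# unit-cube input range so marginal likelihood cannot flatten the surrogate
_LS_BOUNDS = (1e-3, 1e3)
_LS_FIT_BOUNDS = (1e-3, 2.0)


@dataclass
class GPHyperparams:
    signal_variance: float
    lengthscales: np.ndarray  # per input dimension, unit-cube scale
    noise_variance: float
    mean_const: float  # constant prior mean, original response units

    def __post_init__(self) -> None:
        self.lengthscales = np.asarray(self.lengthscales, dtype=float)
        if self.signal_variance <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("signal_variance and lengthscales must be > 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


def matern32_kernel(
    A: np.ndarray, B: np.ndarray, signal_variance: float, lengthscales: np.ndarray
) -> np.ndarray:
    """k(a,b) = s2 * (1 + sqrt(3) r) * exp(-sqrt(3) r), r = ARD-scaled distance."""
    diff = (A[:, None, :] - B[None, :, :]) / lengthscales
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    return signal_variance * (1.0 + _SQRT3 * r) * np.exp(-_SQRT3 * r)


class GPModel:
    """Fitted GP state: scaled training data, hyperparameters, factorization."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        bounds,
        hyperparams: GPHyperparams | None = None,
        nugget: float = 1e-6,
    ):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y) or len(y) < 1:
            raise ValueError("X and y must be aligned and non-empty")
        self.bounds = np.asarray([(float(lo), float(hi)) for lo, hi in bounds])
        if self.bounds.shape != (X.shape[1], 2):
            raise ValueError("bounds must give one (low, high) pair per input dimension")
        self._lo = self.bounds[:, 0]
        self._span = self.bounds[:, 1] - self.bounds[:, 0]
        self.X_raw = X
        self.y_raw = y
        self.Xs = (X - self._lo) / self._span
        self.y_mean = float(y.mean())
        self.y_std = float(y.std())
        if self.y_std <= 0:
            self.y_std = 1.0
        self.ys = (y - self.y_mean) / self.y_std
        if hyperparams is None:
            hyperparams = GPHyperparams(
                signal_variance=1.0,
                lengthscales=np.full(X.shape[1], 0.5),
                noise_variance=nugget,
                mean_const=self.y_mean,
            )
        self.hyperparams = hyperparams
        self._factorize()

    @property
    def n(self) -> int:
        return len(self.y_raw)

    def _scaled_noise(self) -> float:
        # noise stored on the standardized-output scale
        return self.hyperparams.noise_variance

    def _factorize(self) -> None:
        hp = self.hyperparams
        K = matern32_kernel(self.Xs, self.Xs, hp.signal_variance, hp.lengthscales)
        jitter = self._scaled_noise()
        for _ in range(8):
            try:
                self._chol = linalg.cholesky(K + jitter * np.eye(self.n), lower=True)
                break
            except linalg.LinAlgError:
                jitter = max(jitter, 1e-12) * 10.0
        else:
            raise linalg.LinAlgError("kernel matrix not positive definite even with jitter")
        self._alpha = linalg.cho_solve((self._chol, True), self.ys)

    def log_marginal_likelihood(self) -> float:
        return float(
            -0.5 * self.ys @ self._alpha
            - np.sum(np.log(np.diag(self._chol)))
            - 0.5 * self.n * np.log(2 * np.pi)
        )

    def posterior(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd at query points, in original response units."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.Xs.shape[1]:
            raise ValueError(f"query dimension {x.shape[1]} != {self.Xs.shape[1]}")
        xs = (x - self._lo) / self._span
        hp = self.hyperparams
        Ks = matern32_kernel(xs, self.Xs, hp.signal_variance, hp.lengthscales)
        mean_s = Ks @ self._alpha
        v = linalg.solve_triangular(self._chol, Ks.T, lower=True)
        var_s = hp.signal_variance - np.sum(v * v, axis=0)
        var_s = np.maximum(var_s, 0.0)
        mean = self.y_mean + self.y_std * mean_s
        sd = self.y_std * np.sqrt(var_s)
        return mean, sd

    def posterior_at(self, x) -> tuple[float, float]:
        mean, sd = self.posterior(np.asarray(x, dtype=float)[None, :])
        return float(mean[0]), float(sd[0])


def gp_posterior(model: GPModel, x) -> tuple[float, float]:
    """Posterior (mean, sd) at a single point in original units."""
    return model.posterior_at(x)


def _has_conflicting_duplicates(Xs: np.ndarray, ys: np.ndarray, nugget: float) -> bool:
    seen: dict[tuple, float] = {}
    for row, val in zip(np.round(Xs, 10), ys):
        key = tuple(row)
        if key in seen and abs(seen[key] - val) > 10 * np.sqrt(max(nugget, 1e-12)):
            return True
        seen[key] = val
    return False


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    bounds,
    restarts: int = 10,
    seed: int = 0,
    nugget: float = 1e-6,
    estimate_noise: bool = False,
) -> GPModel:
    """Fit GP hyperparameters by marginal-likelihood maximization.

    ``restarts`` seeded multistarts of L-BFGS-B over log signal variance and
    log lengthscales (plus log noise when ``estimate_noise``).  With a single
    training point the prior defaults are kept.
    """
    model = GPModel(X, y, bounds, nugget=nugget)
    if model.n < 2:
        return model
    if not estimate_noise and _has_conflicting_duplicates(model.Xs, model.ys, nugget):
        import warnings

        warnings.warn(
            "duplicate inputs with conflicting outputs under a near-zero nugget; "
            "estimating the noise variance instead"
        )
        estimate_noise = True
    dim = model.Xs.shape[1]
    rng = np.random.default_rng(seed)

    def set_params(theta: np.ndarray) -> None:
        sv = np.exp(theta[0])
        ls = np.exp(theta[1 : 1 + dim])
        nv = np.exp(theta[1 + dim]) if estimate_noise else nugget
        model.hyperparams = GPHyperparams(
            signal_variance=sv, lengthscales=ls, noise_variance=nv, mean_const=model.y_mean
        )

    def neg_lml(theta: np.ndarray) -> float:
        try:
            set_params(theta)
            model._factorize()
            return -model.log_marginal_likelihood()
        except (linalg.LinAlgError, FloatingPointError):
            return 1e25

    lb = [np.log(1e-4)] + [np.log(_LS_FIT_BOUNDS[0])] * dim
    ub = [np.log(1e4)] + [np.log(_LS_FIT_BOUNDS[1])] * dim
    if estimate_noise:
        lb.append(np.log(1e-8))
        ub.append(np.log(1e1))
    opt_bounds = list(zip(lb, ub))

    starts = [np.concatenate([[0.0], np.log(np.full(dim, 0.5)), [np.log(1e-4)] if estimate_noise else []])]
    for _ in range(max(restarts - 1, 0)):
        s = [rng.uniform(np.log(0.1), np.log(10.0))]
        s += list(rng.uniform(np.log(0.05), np.log(2.0), size=dim))
        if estimate_noise:
            s.append(rng.uniform(np.log(1e-6), np.log(1e-1)))
        starts.append(np.array(s))

    best_theta, best_val = None, np.inf
    for s in starts:
        res = optimize.minimize(neg_lml, s, method="L-BFGS-B", bounds=opt_bounds)
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    set_params(best_theta)
    model._factorize()
    return model
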