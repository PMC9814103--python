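"""Gaussian-process regression surrogate over the encoded design space.

The surrogate is a zero-mean GP on standardized yields with a Matérn-5/2
ARD kernel over the full encoded vector (unit-scaled continuous dims and
one-hot dims treated alike) plus i.i.d. Gaussian observation noise.
Hyperparameters — per-dimension lengthscales, signal variance and noise
variance — are fitted by maximizing the log marginal likelihood with
multi-restart L-BFGS-B in log-parameter space.

All linear algebra goes through a Cholesky factorization of the kernel
matrix with an escalating jitter (1e-10 → 1e-6) on failure.  Predictions
are destandardized back to yield percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelConfig",
    "SurrogateModel",
    "Prediction",
    "InsufficientDataError",
    "NumericalError",
    "fit",
    "log_marginal_likelihood",
]

log = logging.getLogger("flowbo.gp")

NOISE_FLOOR = 1e-6  # standardized units
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)
# Lower bound 0.1 (10% of a parameter's range) encodes the assumption that
# reaction-yield surfaces do not vary on scales finer than the lab can set;
# anything smaller lets the evidence collapse into noise-free interpolation
# of replicate-level noise, which destroys the explore/exploit balance.
LENGTHSCALE_BOUNDS = (0.1, 10.0)
SIGNAL_VAR_BOUNDS = (1e-2, 1e2)
NOISE_VAR_BOUNDS = (NOISE_FLOOR, 1.0)


class InsufficientDataError(ValueError):
    """Fewer than two observations — no surrogate can be fitted."""


class NumericalError(RuntimeError):
    """Kernel matrix not positive definite even after jitter escalation."""


@dataclass(frozen=True)
class KernelConfig:
    """Matérn-5/2 ARD kernel hyperparameters (standardized-y units)."""

    signal_variance: float
    lengthscales: np.ndarray  # one per encoded dimension
    noise_variance: float
    kernel_family: str = "matern52"

    def __post_init__(self) -> None:
        ls = np.asarray(self.lengthscales, dtype=float)
        object.__setattr__(self, "lengthscales", ls)
        if self.signal_variance <= 0 or self.noise_variance < NOISE_FLOOR or np.any(ls <= 0):
            raise ValueError("kernel hyperparameters must be positive (noise ≥ floor)")


@dataclass(frozen=True)
class Prediction:
    """Posterior mean and standard deviation, in yield percent."""

    mean: float
    sd: float


def _matern52(X1: np.ndarray, X2: np.ndarray, kernel: KernelConfig) -> np.ndarray:
    r = cdist(X1 / kernel.lengthscales, X2 / kernel.lengthscales)
    s = math.sqrt(5.0) * r
    return kernel.signal_variance * (1.0 + s + s * s / 3.0) * np.exp(-s)


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    for jitter in JITTERS:
        try:
            L = cholesky(K + jitter * np.eye(len(K)), lower=True)
            if jitter > 0:
                log.debug("kernel matrix needed jitter %g", jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            continue
        except Exception:
            continue
    raise NumericalError(
        f"kernel matrix of size {len(K)} not positive definite after jitter "
        f"escalation up to {JITTERS[-1]:g}"
    )


@dataclass(frozen=True)
class SurrogateModel:
    """A fitted GP: training data in encoded space, standardization frame,
    kernel hyperparameters, and the cached Cholesky solve."""

    train_X: np.ndarray
    train_y_std: np.ndarray  # standardized targets
    y_mean: float
    y_sd: float
    kernel: KernelConfig
    L: np.ndarray  # lower Cholesky factor of K + noise*I (+ jitter)
    alpha: np.ndarray  # (K + noise*I)^-1 y_std

    @property
    def n(self) -> int:
        return len(self.train_y_std)

    @property
    def encoded_dim(self) -> int:
        return self.train_X.shape[1]

    def predict(self, X_star: np.ndarray) -> list[Prediction]:
        """Exact GP posterior at each row of ``X_star``, in yield percent."""
        mean, sd = self.predict_arrays(X_star)
        return [Prediction(float(m), float(s)) for m, s in zip(mean, sd)]

    def predict_arrays(self, X_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
        if X_star.shape[1] != self.encoded_dim:
            raise ValueError(
                f"expected {self.encoded_dim} columns, got {X_star.shape[1]}"
            )
        Ks = _matern52(X_star, self.train_X, self.kernel)  # m × n
        mean_std = Ks @ self.alpha
        V = solve_triangular(self.L, Ks.T, lower=True)  # n × m
        var_std = self.kernel.signal_variance - np.sum(V * V, axis=0)
        clipped = var_std < 0
        if np.any(clipped):
            log.debug("clamped %d negative posterior variances", int(clipped.sum()))
        var_std = np.maximum(var_std, 0.0)
        mean = self.y_mean + self.y_sd * mean_std
        sd = self.y_sd * np.sqrt(var_std)
        return mean, sd

    def condition_on(self, x: np.ndarray, y_pct: float) -> "SurrogateModel":
        """Return a model conditioned on one extra observation at fixed
        hyperparameters (used for kriging-believer hallucination)."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        X = np.vstack([self.train_X, x])
        y_std = np.append(self.train_y_std, (y_pct - self.y_mean) / self.y_sd)
        L, alpha = _solve(X, y_std, self.kernel)
        return replace(self, train_X=X, train_y_std=y_std, L=L, alpha=alpha)

    def to_dict(self) -> dict:
        return {
            "train_X": self.train_X.tolist(),
            "train_y_std": self.train_y_std.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "kernel": {
                "signal_variance": self.kernel.signal_variance,
                "lengthscales": self.kernel.lengthscales.tolist(),
                "noise_variance": self.kernel.noise_variance,
                "kernel_family": self.kernel.kernel_family,
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SurrogateModel":
        kernel = KernelConfig(
            signal_variance=float(doc["kernel"]["signal_variance"]),
            lengthscales=np.asarray(doc["kernel"]["lengthscales"], float),
            noise_variance=float(doc["kernel"]["noise_variance"]),
            kernel_family=doc["kernel"].get("kernel_family", "matern52"),
        )
        X = np.asarray(doc["train_X"], float)
        y_std = np.asarray(doc["train_y_std"], float)
        L, alpha = _solve(X, y_std, kernel)
        return cls(
            train_X=X,
            train_y_std=y_std,
            y_mean=float(doc["y_mean"]),
            y_sd=float(doc["y_sd"]),
            kernel=kernel,
            L=L,
            alpha=alpha,
        )


def _solve(X: np.ndarray, y_std: np.ndarray, kernel: KernelConfig):
    K = _matern52(X, X, kernel) + kernel.noise_variance * np.eye(len(X))
    L, _ = _chol_with_jitter(K)
    alpha = cho_solve((L, True), y_std)
    return L, alpha


def log_marginal_likelihood(
    X: np.ndarray, y_std: np.ndarray, kernel: KernelConfig
) -> float:
    """GP evidence log p(y | X, θ) on standardized targets."""
    n = len(y_std)
    L, alpha_ = _solve(X, y_std, kernel)
    return float(
        -0.5 * y_std @ alpha_
        - np.sum(np.log(np.diag(L)))
        - 0.5 * n * math.log(2.0 * math.pi)
    )


def standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-fit standardization; constant targets get sd = 1 so the GP
    degenerates to predicting the constant rather than dividing by zero."""
    y = np.asarray(y, dtype=float)
    y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    if y_sd <= 1e-12:
        y_sd = 1.0
    return (y - y_mean) / y_sd, y_mean, y_sd


def fit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_restarts: int = 5,
    seed: int = 0,
    kernel_overrides: dict | None = None,
) -> SurrogateModel:
    """Fit hyperparameters by maximum marginal likelihood.

    Multi-restart L-BFGS-B in log space: one start at a default
    (lengthscales 0.5, unit signal variance, noise 1e-2) plus seeded
    log-uniform draws within the hyperparameter bounds.  Deterministic
    given (X, y, seed).

    ``kernel_overrides`` may pin any of ``signal_variance``,
    ``lengthscales``, ``noise_variance``; pinned values are excluded from
    optimization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) < 2:
        raise InsufficientDataError("need at least 2 observations to fit a GP")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training data")

    y_std, y_mean, y_sd = standardize(y)
    d = X.shape[1]
    overrides = kernel_overrides or {}

    def build(theta: np.ndarray) -> KernelConfig:
        sv = overrides.get("signal_variance")
        ls = overrides.get("lengthscales")
        nv = overrides.get("noise_variance")
        i = 0
        if sv is None:
            sv = math.exp(theta[i]); i += 1
        if ls is None:
            ls = np.exp(theta[i : i + d]); i += d
        if nv is None:
            nv = math.exp(theta[i]); i += 1
        return KernelConfig(float(sv), np.asarray(ls, float), float(nv))

    free_bounds: list[tuple[float, float]] = []
    default_start: list[float] = []
    if "signal_variance" not in overrides:
        free_bounds.append(tuple(np.log(SIGNAL_VAR_BOUNDS)))
        default_start.append(0.0)
    if "lengthscales" not in overrides:
        free_bounds += [tuple(np.log(LENGTHSCALE_BOUNDS))] * d
        default_start += [math.log(0.5)] * d
    if "noise_variance" not in overrides:
        free_bounds.append(tuple(np.log(NOISE_VAR_BOUNDS)))
        default_start.append(math.log(1e-2))

    def neg_lml(theta: np.ndarray) -> float:
        try:
            return -log_marginal_likelihood(X, y_std, build(theta))
        except NumericalError:
            return 1e10

    rng = np.random.default_rng(seed)
    starts = [np.array(default_start)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in free_bounds])
        )

    best_theta, best_val = None, np.inf
    for x0 in starts:
        if free_bounds:
            res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=free_bounds)
            theta, val = res.x, res.fun
        else:
            theta, val = x0, neg_lml(x0)
        if val < best_val:
            best_theta, best_val = theta, val

    kernel = build(best_theta)
    L, alpha = _solve(X, y_std, kernel)
    log.info(
        "GP fit: n=%d lml=%.3f signal_var=%.3g noise_var=%.3g lengthscales=%s",
        len(y), -best_val, kernel.signal_variance, kernel.noise_variance,
        np.array2string(kernel.lengthscales, precision=3),
    )
    return SurrogateModel(
        train_X=X,
        train_y_std=y_std,
        y_mean=y_mean,
        y_sd=y_sd,
        kernel=kernel,
        L=L,
        alpha=alpha,
    )
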