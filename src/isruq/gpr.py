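"""Single-output Gaussian-process regression with an ARD squared-exponential kernel.

The model is y = f(x) + eps with a zero-mean GP prior on f and independent
Gaussian noise eps ~ N(0, sigma_n^2). The covariance is the radial basis
function kernel with automatic relevance determination (one lengthscale per
input dimension):

    k(x, x') = sigma_f^2 exp(-1/2 sum_i (x_i - x'_i)^2 / l_i^2)

Hyperparameters are set by maximising the log marginal likelihood

    log p(y | X, theta) = -1/2 y^T (K + sigma_n^2 I)^-1 y
                          - 1/2 log|K + sigma_n^2 I| - n/2 log 2 pi

with a gradient-based optimiser (L-BFGS-B in log-hyperparameter space) and
seeded multi-start. Inputs are expected on the unit hypercube; targets are
standardised internally (zero mean, unit variance) and predictions are
returned on the original scale. A noise floor and escalating jitter keep the
Cholesky factorisation of K + sigma_n^2 I well posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "GPHyperparameters",
    "GPModel",
    "ard_rbf",
    "log_marginal_likelihood",
    "fit",
    "predict",
]

#: Lower bound on the noise variance (standardised-target units).
NOISE_FLOOR_VAR = 1e-10
#: Jitter escalation schedule for the Cholesky factorisation.
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)

#: Lengthscale floor (unit-cube units): below the resolution of any
#: realistic design, where signal and noise are not identifiable.
LENGTHSCALE_FLOOR = 5e-2

_LOG_BOUNDS = {
    "sigma_f": (np.log(1e-3), np.log(1e3)),
    "sigma_n": (0.5 * np.log(NOISE_FLOOR_VAR), np.log(1e1)),
    "lengthscale": (np.log(LENGTHSCALE_FLOOR), np.log(1e3)),
}


@dataclass(frozen=True)
class GPHyperparameters:
    """Signal SD, noise SD and per-dimension lengthscales."""

    sigma_f: float
    sigma_n: float
    lengthscales: np.ndarray

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        object.__setattr__(self, "lengthscales", ls)
        if self.sigma_f <= 0 or self.sigma_n < 0 or np.any(ls <= 0):
            raise ValueError("hyperparameters must be strictly positive")

    def to_vector(self) -> np.ndarray:
        """Pack as log-hyperparameters [log sf, log sn, log l_1..l_d]."""
        return np.concatenate(
            ([np.log(self.sigma_f), np.log(max(self.sigma_n, np.sqrt(NOISE_FLOOR_VAR)))],
             np.log(self.lengthscales))
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "GPHyperparameters":
        v = np.asarray(v, dtype=float)
        return cls(sigma_f=float(np.exp(v[0])), sigma_n=float(np.exp(v[1])),
                   lengthscales=np.exp(v[2:]))

    def to_dict(self) -> dict:
        return {
            "sigma_f": self.sigma_f,
            "sigma_n": self.sigma_n,
            "lengthscales": self.lengthscales.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPHyperparameters":
        return cls(d["sigma_f"], d["sigma_n"], np.asarray(d["lengthscales"]))


def ard_rbf(
    x: np.ndarray, x_prime: np.ndarray, theta: GPHyperparameters
) -> np.ndarray:
    """ARD-RBF kernel matrix between two point sets (or two points)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Xp = np.atleast_2d(np.asarray(x_prime, dtype=float))
    ls = theta.lengthscales
    if X.shape[1] != ls.size or Xp.shape[1] != ls.size:
        raise ValueError("input dimension does not match lengthscales")
    diff = X[:, None, :] - Xp[None, :, :]
    sq = np.sum((diff / ls) ** 2, axis=-1)
    K = theta.sigma_f**2 * np.exp(-0.5 * sq)
    if np.ndim(x) == 1 and np.ndim(x_prime) == 1:
        return float(K[0, 0])
    return K


def _chol_with_jitter(Kn: np.ndarray):
    """Cholesky of a noisy kernel matrix, escalating jitter on failure."""
    for j in JITTERS:
        try:
            return cho_factor(Kn + j * np.eye(Kn.shape[0]), lower=True), j
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "kernel matrix not positive definite after jitter escalation "
        f"(max jitter {JITTERS[-1]:g})"
    )


def log_marginal_likelihood(
    X: np.ndarray, y: np.ndarray, theta: GPHyperparameters
) -> float:
    """Gaussian-process log marginal likelihood of targets ``y`` at ``theta``."""
    lml, _ = _lml_and_grad(
        np.atleast_2d(np.asarray(X, float)),
        np.asarray(y, float).ravel(),
        theta.to_vector(),
        want_grad=False,
    )
    return lml


def _lml_and_grad(X: np.ndarray, y: np.ndarray, logv: np.ndarray, want_grad=True):
    """Log marginal likelihood and its gradient w.r.t. log-hyperparameters."""
    n, d = X.shape
    sf2 = np.exp(2.0 * logv[0])
    sn2 = max(np.exp(2.0 * logv[1]), NOISE_FLOOR_VAR)
    ls = np.exp(logv[2:])
    diff = X[:, None, :] - X[None, :, :]
    sq = np.einsum("ijk,k->ij", diff**2, 1.0 / ls**2)
    K = sf2 * np.exp(-0.5 * sq)
    (c, low), jit = _chol_with_jitter(K + sn2 * np.eye(n))
    alpha = cho_solve((c, low), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(c))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    if not want_grad:
        return lml, None
    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv  # dL/dKn = A/2
    grad = np.empty(logv.size)
    grad[0] = float(np.sum(A * K))  # d Kn / d log sf = 2 K
    grad[1] = sn2 * float(np.trace(A))  # d Kn / d log sn = 2 sn^2 I
    AK = A * K
    for i in range(d):
        # d Kn / d log l_i = K * diff_i^2 / l_i^2
        grad[2 + i] = 0.5 * float(np.sum(AK * diff[:, :, i] ** 2)) / ls[i] ** 2
    return lml, grad


@dataclass
class GPModel:
    """Fitted GP: training data, hyperparameters and cached factorisation."""

    X: np.ndarray
    y: np.ndarray
    theta: GPHyperparameters
    y_mean: float
    y_sd: float
    log_marginal: float
    jitter: float = 0.0
    _chol: tuple = None  # (cho_factor output) on standardised targets
    _alpha: np.ndarray = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def _ensure_cache(self) -> None:
        if self._chol is None:
            Kn = ard_rbf(self.X, self.X, self.theta) + max(
                self.theta.sigma_n**2, NOISE_FLOOR_VAR
            ) * np.eye(self.n)
            (c, low), jit = _chol_with_jitter(Kn)
            self._chol = (c, low)
            self.jitter = jit
            ys = (self.y - self.y_mean) / self.y_sd
            self._alpha = cho_solve((c, low), ys)

    def to_dict(self) -> dict:
        return {
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "theta": self.theta.to_dict(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "log_marginal": self.log_marginal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPModel":
        return cls(
            X=np.asarray(d["X"], float),
            y=np.asarray(d["y"], float),
            theta=GPHyperparameters.from_dict(d["theta"]),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            log_marginal=float(d["log_marginal"]),
        )


def _standardise(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(y))
    sd = float(np.std(y))
    if sd < 1e-15:
        sd = 1.0  # constant target: fit residual zeros
    return (y - mu) / sd, mu, sd


def fit(
    X: np.ndarray,
    y: np.ndarray,
    restarts: int = 10,
    seed: int | np.random.Generator = 0,
    maxiter: int = 200,
) -> GPModel:
    """Fit hyperparameters by multi-start maximisation of the marginal likelihood.

    ``X`` should be scaled to the unit hypercube. The first start is a fixed
    heuristic (unit signal, lengthscale 0.5, noise SD 0.1 on standardised
    targets); the remaining ``restarts - 1`` starts draw log-uniform
    lengthscales in [1e-2, 1e1], signal SD in [0.1, 10] and noise SD in
    [1e-4, 1]. Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 2:
        raise ValueError("at least two training points are required")
    if y.size != n:
        raise ValueError("X and y sizes disagree")
    ys, mu, sd = _standardise(y)
    rng = np.random.default_rng(seed)

    starts = [np.concatenate(([0.0, np.log(0.1)], np.full(d, np.log(0.5))))]
    for _ in range(max(0, restarts - 1)):
        starts.append(
            np.concatenate(
                (
                    [rng.uniform(np.log(0.1), np.log(10.0))],
                    [rng.uniform(np.log(1e-4), np.log(1.0))],
                    rng.uniform(np.log(1e-2), np.log(1e1), size=d),
                )
            )
        )
    bounds = (
        [_LOG_BOUNDS["sigma_f"], _LOG_BOUNDS["sigma_n"]]
        + [_LOG_BOUNDS["lengthscale"]] * d
    )

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    failures = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = minimize(
                lambda v: tuple(
                    (-a if a is not None else a)
                    for a in _lml_and_grad(X, ys, v)
                ),
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
        except np.linalg.LinAlgError as exc:
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimisation restarts failed: {failures}"
        )
    theta = GPHyperparameters.from_vector(best.x)
    model = GPModel(
        X=X, y=y, theta=theta, y_mean=mu, y_sd=sd, log_marginal=-float(best.fun)
    )
    model._ensure_cache()
    return model


def predict(
    model: GPModel, x_star: np.ndarray, return_std: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance (or SD) at new inputs.

    mean = k(x*, X) [K + sigma_n^2 I]^-1 y
    var  = k(x*, x*) - k(x*, X) [K + sigma_n^2 I]^-1 k(X, x*)

    Variance is clipped at zero against round-off; returned on the original
    target scale.
    """
    model._ensure_cache()
    single = np.ndim(x_star) == 1
    Xs = np.atleast_2d(np.asarray(x_star, dtype=float))
    Ks = ard_rbf(Xs, model.X, model.theta)  # m x n
    mean_s = Ks @ model._alpha
    c, low = model._chol
    # var = sf^2 - ||L^-1 k*||^2 per column
    v = solve_triangular(c, Ks.T, lower=low, check_finite=False)
    var_s = np.maximum(model.theta.sigma_f**2 - np.sum(v**2, axis=0), 0.0)
    mean = model.y_mean + model.y_sd * mean_s
    var = (model.y_sd**2) * var_s
    out = np.sqrt(var) if return_std else var
    if single:
        return float(mean[0]), float(out[0])
    return mean, out
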