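"""Variance-based global sensitivity analysis (Sobol indices, Saltelli design).

First-order indices S_i = Var_{x_i}(E[f | x_i]) / Var(f) measure the share of
output variance attributable to one input alone; total indices
S_Ti = 1 - Var_{x_~i}(E[f | x_~i]) / Var(f) include all interactions involving
that input. Both are estimated jointly from a Saltelli design: two base
matrices A and B drawn from complementary halves of a scrambled Sobol
sequence, plus the d hybrid matrices A_B^(i) (A with column i taken from B),
at a total cost of (d + 2) N model evaluations. The estimators are the
Saltelli-2010 / Jansen forms:

    S_i  = mean(f_B * (f_ABi - f_A)) / Var(f)
    S_Ti = 1/2 mean((f_A - f_ABi)^2) / Var(f)

with Var(f) computed from the pooled (f_A, f_B) sample. Negative estimates
are reported as-is; they are Monte Carlo noise around small true indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .params import ParameterSpace, scale_unit_to_physical

__all__ = [
    "SaltelliDesign",
    "SobolResult",
    "saltelli_matrices",
    "first_order_indices",
    "total_order_indices",
    "sobol_indices",
    "sensitivity_over_time",
]


@dataclass(frozen=True)
class SaltelliDesign:
    """Base matrices A, B and hybrids A_B^(i) in physical units."""

    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray  # d x N x d stack; AB[i] is A with column i from B
    space: ParameterSpace
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        return (self.d + 2) * self.n

    def all_points(self) -> np.ndarray:
        """Stack [A; B; AB_1; ...; AB_d] for batched model evaluation."""
        return np.vstack([self.A, self.B] + [self.AB[i] for i in range(self.d)])

    def split_evaluations(self, f: np.ndarray):
        """Split batched outputs back into (fA, fB, fAB)."""
        n, d = self.n, self.d
        fA, fB = f[:n], f[n : 2 * n]
        fAB = np.stack([f[(2 + i) * n : (3 + i) * n] for i in range(d)])
        return fA, fB, fAB


@dataclass(frozen=True)
class SobolResult:
    """Per-day, per-parameter first-order and total indices with CIs."""

    days: np.ndarray
    names: tuple[str, ...]
    first_order: np.ndarray  # Nt x d, replicate mean
    total_order: np.ndarray
    first_ci: np.ndarray | None = None  # Nt x d x 2 (2.5%, 97.5%)
    total_ci: np.ndarray | None = None
    n: int = 0
    reps: int = 1
    meta: dict = field(default_factory=dict)


def saltelli_matrices(
    space: ParameterSpace, n: int, seed: int | None = 0
) -> SaltelliDesign:
    """Build the (d + 2) N Saltelli design from a 2d-dimensional Sobol draw."""
    if n < 2:
        raise ValueError("Saltelli design needs N >= 2")
    d = space.d
    eng = qmc.Sobol(2 * d, scramble=seed is not None,
                    seed=None if seed is None else int(seed))
    if seed is None:
        eng.fast_forward(1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        u = eng.random(n)
    A = scale_unit_to_physical(u[:, :d], space)
    B = scale_unit_to_physical(u[:, d:], space)
    AB = np.repeat(A[None, :, :], d, axis=0)
    for i in range(d):
        AB[i, :, i] = B[:, i]
    return SaltelliDesign(A=A, B=B, AB=AB, space=space, seed=seed)


def _pooled_variance(fA: np.ndarray, fB: np.ndarray) -> np.ndarray:
    pooled = np.concatenate([fA, fB], axis=0)
    return pooled.var(axis=0, ddof=1)


def first_order_indices(
    fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
) -> np.ndarray:
    """Saltelli-2010 first-order estimator, vectorised over output columns.

    ``fA``/``fB`` are (N,) or (N, m); ``fAB`` is (d, N) or (d, N, m).
    Returns (d,) or (d, m).
    """
    fA, fB, fAB = (np.asarray(a, dtype=float) for a in (fA, fB, fAB))
    var = _pooled_variance(fA, fB)
    if np.all(var == 0):
        raise ZeroDivisionError("zero output variance: Sobol indices undefined")
    return np.mean(fB * (fAB - fA), axis=1) / var


def total_order_indices(
    fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
) -> np.ndarray:
    """Jansen total-order estimator, vectorised over output columns."""
    fA, fB, fAB = (np.asarray(a, dtype=float) for a in (fA, fB, fAB))
    var = _pooled_variance(fA, fB)
    if np.all(var == 0):
        raise ZeroDivisionError("zero output variance: Sobol indices undefined")
    return 0.5 * np.mean((fA - fAB) ** 2, axis=1) / var


def sobol_indices(
    func,
    space: ParameterSpace,
    n: int,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order and total indices of ``func`` (vectorised rows -> outputs)."""
    design = saltelli_matrices(space, n, seed)
    f = np.asarray(func(design.all_points()), dtype=float)
    fA, fB, fAB = design.split_evaluations(f)
    return (
        first_order_indices(fA, fB, fAB),
        total_order_indices(fA, fB, fAB),
    )


def sensitivity_over_time(
    predict_series,
    space: ParameterSpace,
    n: int,
    reps: int = 1,
    master_seed: int = 0,
    days: np.ndarray | None = None,
) -> SobolResult:
    """Per-day Sobol indices of a time-series model, replicated over scrambles.

    ``predict_series`` maps an (m, d) input matrix to an (m, Nt) response
    matrix. Each replication re-draws the Saltelli design with a distinct
    scramble seed derived from ``master_seed``; 95% confidence intervals are
    across-replicate percentiles.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(reps)
    ]
    firsts, totals = [], []
    for s in rep_seeds:
        S, ST = sobol_indices(predict_series, space, n, seed=s)
        firsts.append(S.T)  # Nt x d
        totals.append(ST.T)
    firsts = np.stack(firsts)
    totals = np.stack(totals)
    if days is None:
        days = np.arange(firsts.shape[1], dtype=float)

    def ci(stack):
        if reps < 2:
            return None
        return np.stack(
            [np.percentile(stack, 2.5, axis=0), np.percentile(stack, 97.5, axis=0)],
            axis=-1,
        )

    return SobolResult(
        days=np.asarray(days, dtype=float),
        names=space.names,
        first_order=firsts.mean(axis=0),
        total_order=totals.mean(axis=0),
        first_ci=ci(firsts),
        total_ci=ci(totals),
        n=int(n),
        reps=int(reps),
        meta={"master_seed": int(master_seed), "rep_seeds": rep_seeds},
    )
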