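"""Proper orthogonal decomposition of time-series model responses.

A snapshot matrix stacks daily response vectors (one column per model run).
Its thin SVD gives an orthonormal basis of the response space; the basis is
truncated at the smallest rank whose relative energy — the fraction of total
squared singular-value mass captured — exceeds a threshold (99.9% in the
restenosis study). Responses are projected onto the truncated basis and
reconstructed from their coefficients. No mean-centering is applied: the
decomposition operates on raw responses so the energy ratio refers to the
uncentred second moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnapshotMatrix",
    "PODBasis",
    "build_snapshots",
    "decompose",
    "relative_energy",
    "select_rank",
    "project",
    "reconstruct",
    "pod_relative_error",
]


@dataclass(frozen=True)
class SnapshotMatrix:
    """Nt x Ns matrix whose columns are response time series."""

    S: np.ndarray
    indices: np.ndarray | None = None  # dataset rows used, for provenance

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.ndim != 2 or S.shape[1] < 1:
            raise ValueError("snapshot matrix must be 2-D with >= 1 column")
        if not np.all(np.isfinite(S)):
            raise ValueError("snapshot matrix contains non-finite entries")


@dataclass(frozen=True)
class PODBasis:
    """Truncated left-singular basis with all singular values retained."""

    phi: np.ndarray  # Nt x k, orthonormal columns
    singular_values: np.ndarray  # length Ns, non-increasing
    k: int
    energy_threshold: float | None = None
    snapshot_indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.phi.shape[1] != self.k:
            raise ValueError("basis width must equal k")

    @property
    def n_t(self) -> int:
        return self.phi.shape[0]

    @property
    def relative_energy(self) -> float:
        return relative_energy(self.singular_values, self.k)

    def truncate(self, k: int) -> "PODBasis":
        if not 1 <= k <= self.phi.shape[1]:
            raise ValueError("truncation rank out of range")
        return PODBasis(
            phi=self.phi[:, :k],
            singular_values=self.singular_values,
            k=k,
            energy_threshold=self.energy_threshold,
            snapshot_indices=self.snapshot_indices,
        )


def build_snapshots(
    qoi_matrix: np.ndarray, m: int, seed: int | np.random.Generator = 0
) -> SnapshotMatrix:
    """Select ``m`` responses uniformly without replacement as snapshot columns.

    ``qoi_matrix`` is n x Nt (one row per model run); the result is Nt x m.
    """
    qoi_matrix = np.asarray(qoi_matrix, dtype=float)
    n = qoi_matrix.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"snapshot count m={m} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False)
    return SnapshotMatrix(S=qoi_matrix[idx].T, indices=idx)


def decompose(snapshots: SnapshotMatrix | np.ndarray) -> PODBasis:
    """Thin SVD of the snapshot matrix; returns the untruncated basis."""
    if isinstance(snapshots, SnapshotMatrix):
        S, idx = snapshots.S, snapshots.indices
    else:
        S, idx = np.asarray(snapshots, dtype=float), None
    U, sig, _ = np.linalg.svd(S, full_matrices=False)
    return PODBasis(
        phi=U, singular_values=sig, k=U.shape[1], snapshot_indices=idx
    )


def relative_energy(singular_values: np.ndarray, k: int) -> float:
    """Fraction of squared singular-value mass in the leading ``k`` modes."""
    sig2 = np.asarray(singular_values, dtype=float) ** 2
    total = sig2.sum()
    if total == 0:
        raise ValueError("relative energy undefined for an all-zero snapshot matrix")
    if not 1 <= k <= sig2.size:
        raise ValueError("rank out of range")
    return float(sig2[:k].sum() / total)


def select_rank(basis: PODBasis, threshold: float = 0.999) -> int:
    """Smallest rank whose relative energy reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    sig2 = basis.singular_values**2
    cum = np.cumsum(sig2) / sig2.sum()
    k = int(np.searchsorted(cum, threshold - 1e-15) + 1)
    return min(k, sig2.size)


def project(basis: PODBasis, y: np.ndarray) -> np.ndarray:
    """Coefficients alpha = Phi^T y (vector y or matrix of row responses)."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != basis.n_t:
        raise ValueError(
            f"response length {y.shape[-1]} does not match basis rows {basis.n_t}"
        )
    return y @ basis.phi


def reconstruct(basis: PODBasis, alpha: np.ndarray) -> np.ndarray:
    """Response y_hat = Phi alpha (vector alpha or matrix of row coefficients)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape[-1] != basis.k:
        raise ValueError(
            f"coefficient length {alpha.shape[-1]} does not match rank {basis.k}"
        )
    return alpha @ basis.phi.T


def pod_relative_error(basis: PODBasis, ys: np.ndarray) -> float:
    """Mean relative L2 projection error over a set of responses.

    mean_i ||y_i - Phi Phi^T y_i|| / ||y_i||. Raises on any zero-norm response.
    """
    ys = np.atleast_2d(np.asarray(ys, dtype=float))
    norms = np.linalg.norm(ys, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm response in validation set")
    resid = ys - reconstruct(basis, project(basis, ys))
    return float(np.mean(np.linalg.norm(resid, axis=1) / norms))
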