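"""POD + Gaussian-process surrogate of the time-dependent restenosis response.

Training: a snapshot matrix of randomly chosen training responses is
decomposed by SVD and truncated at the 99.9% relative-energy rank k; every
training response is projected onto the k modes, and one single-output GP is
fitted per projection coefficient on the (unit-cube-scaled) uncertain inputs.
Prediction: the k coefficient GPs are evaluated at a new input and the
response is reconstructed through the basis. The coefficient GPs are treated
as independent, so the predictive variance of the reconstruction is
Var(y_t) = sum_j Var(alpha_j) phi_jt^2 — an approximation, recorded as such.

Validation: k-fold cross-validation reporting the mean relative L2 errors of
the pure POD projection (e_POD) and the full GP reconstruction (e_GP) on the
held-out folds; the POD basis is re-fitted inside each fold (strict held-out
protocol).

Predicted series can violate the monotonicity that physical lumen series
satisfy (ACSA non-increasing, MRAL non-decreasing); a post-hoc isotonic
projection is applied only when requested and the raw series is kept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gpr, pod
from .emulator import Dataset
from .params import ParameterSpace, scale_physical_to_unit

__all__ = ["SurrogateModel", "QoISurrogate", "CVReport", "train",
           "predict_qoi", "cross_validate", "isotonic_cleanup"]

QOI_MONOTONE = {"acsa": "non-increasing", "mral": "non-decreasing"}


@dataclass
class QoISurrogate:
    """POD basis plus one GP per retained coefficient, for a single QoI."""

    qoi: str
    basis: pod.PODBasis
    gps: list
    energy_threshold: float

    def __post_init__(self) -> None:
        if len(self.gps) != self.basis.k:
            raise ValueError("one GP per retained mode is required")


@dataclass
class SurrogateModel:
    """Per-QoI surrogates sharing one input space and training design."""

    space: ParameterSpace
    per_qoi: dict
    provenance: dict = field(default_factory=dict)

    @property
    def qois(self) -> tuple:
        return tuple(self.per_qoi)

    def save(self, directory: str | Path) -> None:
        """Write a portable model archive (JSON metadata + one .npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"space": self.space.to_dict(), "provenance": self.provenance,
                "qois": {}}
        arrays = {}
        for name, qs in self.per_qoi.items():
            meta["qois"][name] = {
                "k": qs.basis.k,
                "energy_threshold": qs.energy_threshold,
                "gp_meta": [
                    {"theta": gp.theta.to_dict(), "y_mean": gp.y_mean,
                     "y_sd": gp.y_sd, "log_marginal": gp.log_marginal}
                    for gp in qs.gps
                ],
            }
            arrays[f"{name}_phi"] = qs.basis.phi
            arrays[f"{name}_sv"] = qs.basis.singular_values
            if qs.basis.snapshot_indices is not None:
                arrays[f"{name}_snap_idx"] = qs.basis.snapshot_indices
            arrays[f"{name}_X"] = qs.gps[0].X
            arrays[f"{name}_y"] = np.stack([gp.y for gp in qs.gps])
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "SurrogateModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        arrays = np.load(directory / "arrays.npz")
        per_qoi = {}
        for name, qmeta in meta["qois"].items():
            basis = pod.PODBasis(
                phi=arrays[f"{name}_phi"],
                singular_values=arrays[f"{name}_sv"],
                k=int(qmeta["k"]),
                energy_threshold=qmeta["energy_threshold"],
                snapshot_indices=arrays.get(f"{name}_snap_idx"),
            )
            X = arrays[f"{name}_X"]
            ys = arrays[f"{name}_y"]
            gps = []
            for j, gmeta in enumerate(qmeta["gp_meta"]):
                gp = gpr.GPModel(
                    X=X, y=ys[j],
                    theta=gpr.GPHyperparameters.from_dict(gmeta["theta"]),
                    y_mean=float(gmeta["y_mean"]), y_sd=float(gmeta["y_sd"]),
                    log_marginal=float(gmeta["log_marginal"]),
                )
                gps.append(gp)
            per_qoi[name] = QoISurrogate(
                qoi=name, basis=basis, gps=gps,
                energy_threshold=float(qmeta["energy_threshold"]),
            )
        return cls(
            space=ParameterSpace.from_dict(meta["space"]),
            per_qoi=per_qoi,
            provenance=meta["provenance"],
        )


@dataclass(frozen=True)
class CVReport:
    """Cross-validation errors per QoI: mean and per-fold e_POD / e_GP."""

    folds: int
    repetitions: int
    seed: int
    e_pod: dict  # qoi -> mean over folds and reps
    e_gp: dict
    per_fold: dict  # qoi -> {"e_pod": [...], "e_gp": [...]}
    e_pod_sum: dict  # raw sums over validation samples (unaveraged form)
    e_gp_sum: dict

    def to_dict(self) -> dict:
        return {
            "folds": self.folds, "repetitions": self.repetitions,
            "seed": self.seed, "e_pod": self.e_pod, "e_gp": self.e_gp,
            "per_fold": self.per_fold, "e_pod_sum": self.e_pod_sum,
            "e_gp_sum": self.e_gp_sum,
        }


def _dataset_digest(dataset: Dataset) -> str:
    h = hashlib.sha256()
    for a in (dataset.samples.values, dataset.acsa, dataset.mral):
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _train_one_qoi(
    qoi: str,
    X_unit: np.ndarray,
    Y: np.ndarray,
    n_snapshots: int,
    energy_threshold: float,
    rng: np.random.Generator,
    restarts: int,
) -> QoISurrogate:
    snap = pod.build_snapshots(Y, n_snapshots, seed=rng)
    basis = pod.decompose(snap)
    k = pod.select_rank(basis, energy_threshold)
    basis = basis.truncate(k)
    coeffs = pod.project(basis, Y)  # n x k
    gps = [
        gpr.fit(X_unit, coeffs[:, j], restarts=restarts, seed=rng)
        for j in range(k)
    ]
    return QoISurrogate(qoi=qoi, basis=basis, gps=gps,
                        energy_threshold=energy_threshold)


def train(
    dataset: Dataset,
    n_snapshots: int = 100,
    energy_threshold: float = 0.999,
    seed: int = 0,
    restarts: int = 10,
    qois: tuple = ("acsa", "mral"),
) -> SurrogateModel:
    """Fit the per-QoI POD bases and coefficient GPs on a training dataset."""
    if not 1 <= n_snapshots <= dataset.n:
        raise ValueError("n_snapshots must be within the dataset size")
    space = dataset.samples.space
    X_unit = scale_physical_to_unit(dataset.samples.values, space)
    rng = np.random.default_rng(seed)
    per_qoi = {
        q: _train_one_qoi(q, X_unit, dataset.qoi(q), n_snapshots,
                          energy_threshold, rng, restarts)
        for q in qois
    }
    return SurrogateModel(
        space=space,
        per_qoi=per_qoi,
        provenance={
            "dataset_digest": _dataset_digest(dataset),
            "dataset_provenance": dataset.provenance,
            "n_snapshots": int(n_snapshots),
            "energy_threshold": float(energy_threshold),
            "seed": int(seed) if isinstance(seed, (int, np.integer)) else None,
            "restarts": int(restarts),
            "ranks": {q: per_qoi[q].basis.k for q in per_qoi},
        },
    )


def isotonic_cleanup(y: np.ndarray, direction: str) -> np.ndarray:
    """Project a series onto the monotone cone (pool-adjacent-violators).

    Applied row-wise for 2-D input. ``direction`` is "non-increasing" or
    "non-decreasing".
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        return np.stack([isotonic_cleanup(r, direction) for r in y])
    sign = {"non-decreasing": 1.0, "non-increasing": -1.0}[direction]
    z = sign * y
    # pool adjacent violators, uniform weights
    vals, counts = [], []
    for v in z:
        vals.append(v); counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, c2 = vals.pop(), counts.pop()
            v1, c1 = vals.pop(), counts.pop()
            vals.append((v1 * c1 + v2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    out = np.repeat(vals, counts)
    return sign * out


def predict_qoi(
    model: SurrogateModel,
    x_star: np.ndarray,
    qoi: str = "acsa",
    return_variance: bool = False,
    monotone: bool = False,
):
    """Predict the daily QoI series at new inputs.

    Coefficient means from each GP are reconstructed through the POD basis;
    per-day variance sums the per-coefficient predictive variances weighted
    by the squared basis entries (independence approximation). Inputs
    outside the training box trigger an extrapolation warning, not an error.
    With ``monotone=True`` the series is isotonically projected onto the
    QoI's physical cone (and MRAL clipped into [0, 1)).
    """
    qs = model.per_qoi[qoi]
    single = np.ndim(x_star) == 1
    X = np.atleast_2d(np.asarray(x_star, dtype=float))
    if not model.space.contains(X):
        import warnings

        warnings.warn("input outside the training box: extrapolating",
                      stacklevel=2)
    U = np.clip(scale_physical_to_unit(X, model.space), -10, 10)
    means = np.empty((X.shape[0], qs.basis.k))
    if return_variance:
        cvars = np.empty_like(means)
    for j, gp in enumerate(qs.gps):
        m, v = gpr.predict(gp, U)
        means[:, j] = m
        if return_variance:
            cvars[:, j] = v
    y = pod.reconstruct(qs.basis, means)
    if monotone:
        y = isotonic_cleanup(y, QOI_MONOTONE[qoi])
        if qoi == "mral":
            y = np.clip(y, 0.0, 1.0 - 1e-12)
    if return_variance:
        var = cvars @ (qs.basis.phi.T**2)
        if single:
            return y[0], var[0]
        return y, var
    return y[0] if single else y


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.permutation(n)
    return np.array_split(idx, folds)


def cross_validate(
    dataset: Dataset,
    folds: int = 4,
    repetitions: int = 1,
    seed: int = 0,
    n_snapshots: int = 100,
    energy_threshold: float = 0.999,
    restarts: int = 10,
    qois: tuple = ("acsa", "mral"),
) -> CVReport:
    """K-fold cross-validation of the full POD + GP pipeline.

    Folds are a seeded random partition (sizes differing by at most one);
    within each fold the snapshot selection, basis and every GP are refitted
    on the training part only. e_POD and e_GP are the held-out mean relative
    L2 errors; the unaveraged sums are recorded alongside.
    """
    if dataset.n < folds:
        raise ValueError("dataset smaller than the number of folds")
    rng = np.random.default_rng(seed)
    per_fold = {q: {"e_pod": [], "e_gp": [], "fold_size": []} for q in qois}
    for _ in range(repetitions):
        assignment = _fold_assignment(dataset.n, folds, rng)
        for fold_idx in assignment:
            if fold_idx.size < 2:
                raise ValueError("fold with fewer than 2 samples")
            mask = np.ones(dataset.n, dtype=bool)
            mask[fold_idx] = False
            train_ds = Dataset(
                samples=type(dataset.samples)(
                    values=dataset.samples.values[mask],
                    space=dataset.samples.space,
                    provenance=dataset.samples.provenance,
                ),
                acsa=dataset.acsa[mask],
                mral=dataset.mral[mask],
                days=dataset.days,
            )
            m = min(n_snapshots, train_ds.n)
            model = train(train_ds, m, energy_threshold, seed=rng,
                          restarts=restarts, qois=qois)
            for q in qois:
                Y_val = dataset.qoi(q)[fold_idx]
                qs = model.per_qoi[q]
                e_pod = pod.pod_relative_error(qs.basis, Y_val)
                Y_hat = predict_qoi(model, dataset.samples.values[fold_idx],
                                    qoi=q)
                rel = (np.linalg.norm(Y_val - Y_hat, axis=1)
                       / np.linalg.norm(Y_val, axis=1))
                per_fold[q]["e_pod"].append(float(e_pod))
                per_fold[q]["e_gp"].append(float(np.mean(rel)))
                per_fold[q]["fold_size"].append(int(fold_idx.size))

    def _sum(q, key):  # raw, unaveraged sum over validation samples
        sizes = np.asarray(per_fold[q]["fold_size"], dtype=float)
        return float(np.sum(np.asarray(per_fold[q][key]) * sizes) / repetitions)

    return CVReport(
        folds=folds,
        repetitions=repetitions,
        seed=seed if isinstance(seed, (int, np.integer)) else -1,
        e_pod={q: float(np.mean(per_fold[q]["e_pod"])) for q in qois},
        e_gp={q: float(np.mean(per_fold[q]["e_gp"])) for q in qois},
        per_fold=per_fold,
        e_pod_sum={q: _sum(q, "e_pod") for q in qois},
        e_gp_sum={q: _sum(q, "e_gp") for q in qois},
    )
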