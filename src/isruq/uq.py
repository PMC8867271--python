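"""Forward uncertainty propagation through the surrogate.

Quasi-Monte Carlo samples of the uncertain inputs are pushed through the
trained surrogate; per-day summary statistics (mean, SD, CV), central
percentile bands, histogram/KDE densities at selected days and the fraction
of restenotic samples (maximum relative area loss at or above a 50%
occlusion threshold) are estimated, optionally replicated over independent
Sobol scramblings to quantify estimator spread.

Conventions: "percentile bands" are central coverage intervals, i.e. the
symmetric quantile pair [(1-c)/2, (1+c)/2]; the SD is across qMC samples
(the across-replicate spread is reported separately); the CV is kept as a
fraction internally and formatted as a percentage only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .params import ParameterSpace, sobol_samples
from .surrogate import SurrogateModel, predict_qoi

__all__ = [
    "UQResult",
    "run_uq",
    "moments_and_cv",
    "percentile_bands",
    "restenosis_fraction",
    "replicate_uq",
    "restenosis_scatter",
]

RESTENOSIS_THRESHOLD = 0.5
DEFAULT_COVERAGES = (0.50, 0.75, 0.95)


@dataclass(frozen=True)
class UQResult:
    """Per-day UQ summaries for both QoIs, with replication spread."""

    days: np.ndarray
    n: int
    reps: int
    master_seed: int
    mean: dict  # qoi -> Nt vector (pooled over replicates)
    sd: dict
    cv: dict
    bands: dict  # qoi -> {coverage: (lo Nt, hi Nt)}
    restenosis: np.ndarray  # Nt vector, fraction of samples >= threshold
    restenosis_threshold: float
    replicate_sd: dict  # qoi -> {"mean": Nt, "sd": Nt, "cv": Nt}
    densities: dict = field(default_factory=dict)  # qoi -> day -> density dict


def run_uq(
    model: SurrogateModel,
    space: ParameterSpace | None = None,
    n: int = 10_000,
    seed: int = 0,
    monotone: bool = True,
) -> dict:
    """Evaluate the surrogate on an n-point Sobol design.

    Returns ``{"inputs": SampleMatrix, "acsa": n x Nt, "mral": n x Nt}``.
    """
    space = space or model.space
    samples = sobol_samples(space, n, scramble_seed=seed)
    out = {"inputs": samples}
    for q in model.qois:
        out[q] = predict_qoi(model, samples.values, qoi=q, monotone=monotone)
    return out


def moments_and_cv(samples: np.ndarray):
    """Column-wise mean, unbiased SD and CV of an N x Nt sample matrix."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("at least two samples are required")
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    cv = np.full_like(mean, np.nan)
    nonzero = mean != 0
    cv[nonzero] = sd[nonzero] / np.abs(mean[nonzero])
    if np.any(~nonzero & (sd > 0)):
        raise ZeroDivisionError("CV undefined where the mean is zero")
    cv[~nonzero] = 0.0
    return mean, sd, cv


def percentile_bands(
    samples: np.ndarray, coverages=DEFAULT_COVERAGES
) -> dict:
    """Central coverage bands per day: coverage c -> (lo, hi) quantile rows."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 20:
        raise ValueError("at least 20 samples are required for bands")
    bands = {}
    for c in coverages:
        lo = np.quantile(samples, (1 - c) / 2, axis=0)
        hi = np.quantile(samples, (1 + c) / 2, axis=0)
        bands[float(c)] = (lo, hi)
    return bands


def restenosis_fraction(
    mral_samples: np.ndarray,
    threshold: float = RESTENOSIS_THRESHOLD,
    day: int | None = None,
):
    """Fraction of samples whose MRAL reaches the occlusion threshold.

    With ``day=None`` the full per-day vector is returned.
    """
    mral_samples = np.atleast_2d(np.asarray(mral_samples, dtype=float))
    frac = np.mean(mral_samples >= threshold, axis=0)
    if day is None:
        return frac
    return float(frac[day])


def _density(values: np.ndarray, bins: int = 50) -> dict:
    hist, edges = np.histogram(values, bins=bins, density=True)
    out = {"bin_edges": edges.tolist(), "density": hist.tolist()}
    if np.std(values) > 0:
        kde = gaussian_kde(values)  # Scott bandwidth
        grid = np.linspace(values.min(), values.max(), 200)
        out["kde_grid"] = grid.tolist()
        out["kde"] = kde(grid).tolist()
    return out


def replicate_uq(
    model: SurrogateModel,
    space: ParameterSpace | None = None,
    n: int = 10_000,
    reps: int = 10,
    master_seed: int = 0,
    density_days=(5, 10, 15, 20, 30),
    restenosis_threshold: float = RESTENOSIS_THRESHOLD,
) -> UQResult:
    """Replicated qMC uncertainty estimation.

    Each replicate redraws the Sobol design with a distinct scramble seed
    derived from ``master_seed``. Point statistics are pooled over all
    replicates; the across-replicate SD of each per-day estimate is reported
    as the estimator spread.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    space = space or model.space
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(reps)
    ]
    per_rep = {q: {"mean": [], "sd": [], "cv": []} for q in model.qois}
    pooled = {q: [] for q in model.qois}
    for s in rep_seeds:
        out = run_uq(model, space, n, seed=s)
        for q in model.qois:
            m, sd, cv = moments_and_cv(out[q])
            per_rep[q]["mean"].append(m)
            per_rep[q]["sd"].append(sd)
            per_rep[q]["cv"].append(cv)
            pooled[q].append(out[q])
    pooled = {q: np.vstack(v) for q, v in pooled.items()}
    days = np.arange(pooled[model.qois[0]].shape[1], dtype=float)

    mean, sd, cv, bands, densities, rep_spread = {}, {}, {}, {}, {}, {}
    for q in model.qois:
        m, s_, c = moments_and_cv(pooled[q])
        mean[q], sd[q], cv[q] = m, s_, c
        bands[q] = percentile_bands(pooled[q])
        densities[q] = {
            int(d): _density(pooled[q][:, int(d)]) for d in density_days
        }
        rep_spread[q] = {
            stat: np.std(np.stack(per_rep[q][stat]), axis=0, ddof=1)
            if reps > 1 else np.zeros_like(mean[q])
            for stat in ("mean", "sd", "cv")
        }
    resten = restenosis_fraction(pooled["mral"], restenosis_threshold)
    return UQResult(
        days=days, n=int(n), reps=int(reps), master_seed=int(master_seed),
        mean=mean, sd=sd, cv=cv, bands=bands,
        restenosis=resten, restenosis_threshold=float(restenosis_threshold),
        replicate_sd=rep_spread, densities=densities,
    )


def restenosis_scatter(
    inputs: np.ndarray,
    mral_samples: np.ndarray,
    day: int,
    threshold: float = RESTENOSIS_THRESHOLD,
    names: tuple | None = None,
    bins: int = 20,
):
    """Inputs of the samples that are restenotic at ``day``, with histograms.

    Returns ``(subset, histograms)`` where ``histograms`` maps parameter name
    (or column index) to a density-normalised histogram dict. An empty subset
    produces empty histograms and a warning.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    mral_samples = np.atleast_2d(np.asarray(mral_samples, dtype=float))
    mask = mral_samples[:, day] >= threshold
    subset = inputs[mask]
    if names is None:
        names = tuple(str(j) for j in range(inputs.shape[1]))
    hists = {}
    if subset.shape[0] == 0:
        import warnings

        warnings.warn(
            f"no samples reach MRAL >= {threshold} at day {day}", stacklevel=2
        )
        return subset, {nm: {"bin_edges": [], "density": []} for nm in names}
    for j, nm in enumerate(names):
        hist, edges = np.histogram(subset[:, j], bins=bins, density=True)
        hists[nm] = {"bin_edges": edges.tolist(), "density": hist.tolist()}
    return subset, hists
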