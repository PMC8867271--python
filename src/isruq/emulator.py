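"""Phenomenological per-slice neointimal growth emulator.

This module is the data generator of the study: a cheap, lumped model of
post-stenting neointimal growth in a stented coronary segment, standing in
for the full three-dimensional multiscale simulator. The vessel is a stack of
``n_slices`` independent cross-sections ("slices") with initial lumen areas
drawn around 3.17 mm^2 (the post-deployment lumen of a 2 mm vessel). Per
slice, the neointimal area N_i(t) grows according to

    dN_i/dt = G * S_i(t) * (1 - E(t) * I(v, A_i)) * (1 - N_i / (N_max * A_i(0)))

where

* ``E(t)`` is the endothelium coverage: linear to 59% over the first 3 days,
  then linear to 100% at the regeneration time ``T_regen`` (an uncertain
  input), constant 1 afterwards;
* ``I(v, A)`` is a logistic wall-shear inhibition factor: the wall shear
  surrogate ``tau = v / r^3`` (Poiseuille scaling, r the lumen radius of the
  slice) is mapped through ``1 / (1 + exp(-k_tau (tau - tau0)))``, so high
  flow velocity or an already-narrowed lumen shuts growth down once the
  endothelium has healed;
* ``S_i(t)`` is a seeding factor: a fast initial ramp, an exponentially
  decaying fenestration burst (more fenestration in the internal elastic
  lamina lets more smooth muscle cells through early on), a strain-excess
  term active when the fixed deployment strain exceeds the bond-breaking
  threshold strain, and a fixed per-slice lognormal-free multiplicative
  noise term (1 + eta_i).

The lumen area is A_i(t) = A_i(0) - N_i(t), integrated by explicit Euler.
Quantities of interest are the slice-average lumen area (ACSA, mm^2) and the
maximum relative area loss over slices (MRAL, dimensionless), reported on a
daily grid.

The kinetic constants are calibration knobs; the defaults were fixed once by
a coarse grid search against distribution-level behaviour (see the methods
note) and are not fitted to data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .params import ParameterSpace, SampleMatrix, default_space, sobol_samples

__all__ = [
    "EmulatorConfig",
    "LumenSeries",
    "Dataset",
    "endothelium_coverage",
    "shear_inhibition",
    "simulate",
    "compute_acsa",
    "compute_mral",
    "generate_dataset",
]


@dataclass(frozen=True)
class EmulatorConfig:
    """Geometry, kinetics and numerics of the growth emulator.

    Units: areas mm^2, times days, velocity m/s, growth rate mm^2/day.
    """

    n_slices: int = 100
    initial_area_mean: float = 3.17
    initial_area_sd: float = 0.04
    horizon: float = 30.0
    dt: float = 0.1
    G: float = 0.33  # max growth rate, mm^2/day
    N_frac_max: float = 0.68  # max neointimal fraction of initial area
    tau0: float = 0.42  # shear-inhibition threshold, v / r^3 units
    k_tau: float = 1200.0  # logistic steepness of shear inhibition
    beta_f: float = 0.13  # fenestration burst gain (per % fenestration)
    t_f: float = 2.5  # fenestration burst decay time, days
    beta_eps: float = 0.25  # strain-excess gain
    eps_dep: float = 0.55  # fixed deployment strain
    growth_noise_sd: float = 0.08  # per-slice multiplicative noise SD

    #: fields that may legitimately be zero (no growth / no noise / no gain)
    _NONNEGATIVE = frozenset(
        {"G", "beta_f", "beta_eps", "growth_noise_sd", "initial_area_sd"}
    )

    def __post_init__(self) -> None:
        for key, v in asdict(self).items():
            if key in self._NONNEGATIVE:
                if v < 0:
                    raise ValueError(f"EmulatorConfig.{key} must be >= 0")
            elif isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"EmulatorConfig.{key} must be positive")
        if self.N_frac_max >= 1:
            raise ValueError("N_frac_max must be < 1")
        steps_per_day = 1.0 / self.dt
        if abs(steps_per_day - round(steps_per_day)) > 1e-9:
            raise ValueError("dt must divide 1.0 day")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EmulatorConfig":
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class LumenSeries:
    """Per-slice lumen areas on the daily grid (n_slices x Nt, mm^2)."""

    areas: np.ndarray
    days: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", a)
        if np.any(a <= 0):
            raise ValueError("lumen areas must stay positive")
        if np.any(np.diff(a, axis=1) > 1e-12):
            raise ValueError("lumen areas must be non-increasing in time")

    @property
    def initial(self) -> np.ndarray:
        return self.areas[:, 0]


@dataclass(frozen=True)
class Dataset:
    """A training design with its two QoI matrices and provenance."""

    samples: SampleMatrix
    acsa: np.ndarray  # n x Nt, mm^2
    mral: np.ndarray  # n x Nt, dimensionless
    days: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.samples.n
        if self.acsa.shape[0] != n or self.mral.shape[0] != n:
            raise ValueError("QoI row counts do not match the sample matrix")
        if self.acsa.shape != self.mral.shape:
            raise ValueError("QoI matrices must share a shape")

    @property
    def n(self) -> int:
        return self.samples.n

    @property
    def n_t(self) -> int:
        return self.acsa.shape[1]

    def qoi(self, name: str) -> np.ndarray:
        if name not in ("acsa", "mral"):
            raise KeyError(f"unknown QoI {name!r}; expected 'acsa' or 'mral'")
        return getattr(self, name)


def endothelium_coverage(t, T_regen: float):
    """Endothelial coverage fraction at time ``t`` (days).

    Linear to 59% over the first 3 days, then linear to full coverage at
    ``T_regen``, constant afterwards.
    """
    if T_regen <= 3:
        raise ValueError("regeneration time must exceed the 3-day fast phase")
    t = np.asarray(t, dtype=float)
    early = 0.59 * t / 3.0
    late = 0.59 + 0.41 * (t - 3.0) / (T_regen - 3.0)
    cov = np.where(t <= 3.0, early, np.minimum(late, 1.0))
    return float(cov) if cov.ndim == 0 else cov


def shear_inhibition(v: float, area, config: EmulatorConfig):
    """Logistic growth-inhibition factor from the wall-shear surrogate v / r^3."""
    if v <= 0:
        raise ValueError("flow velocity must be positive")
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("lumen area must be positive")
    r = np.sqrt(area / np.pi)
    tau = v / r**3
    z = np.clip(config.k_tau * (tau - config.tau0), -700, 700)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def _seeding_noise(config: EmulatorConfig, rng: np.random.Generator) -> np.ndarray:
    eta = rng.normal(0.0, config.growth_noise_sd, size=config.n_slices)
    return np.maximum(1.0 + eta, 0.0)


def simulate(
    params: np.ndarray,
    config: EmulatorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> LumenSeries:
    """Run the growth emulator for one parameter vector.

    ``params`` = (T_regen [day], v [m/s], eps_threshold [-], fenestration [%]).
    Deterministic given ``seed``. Returns per-slice areas on the daily grid.
    """
    config = config or EmulatorConfig()
    T_regen, v, eps_thr, fen_pct = (float(p) for p in np.asarray(params, float))
    rng = np.random.default_rng(seed)

    A0 = rng.normal(config.initial_area_mean, config.initial_area_sd,
                    size=config.n_slices)
    A0 = np.maximum(A0, 0.1 * config.initial_area_mean)
    noise = _seeding_noise(config, rng)
    strain_gain = 1.0 + config.beta_eps * max(0.0, config.eps_dep - eps_thr)
    N_max = config.N_frac_max * A0

    n_days = int(round(config.horizon)) + 1
    steps_per_day = int(round(1.0 / config.dt))
    areas = np.empty((config.n_slices, n_days))
    areas[:, 0] = A0

    N = np.zeros(config.n_slices)
    t = 0.0
    for day in range(1, n_days):
        for _ in range(steps_per_day):
            A = A0 - N
            E = endothelium_coverage(t, T_regen)
            inhib = shear_inhibition(v, A, config)
            seed_factor = (
                (1.0 - np.exp(-t / 0.5))
                * (1.0 + config.beta_f * fen_pct * np.exp(-t / config.t_f))
                * strain_gain
                * noise
            )
            dN = (
                config.G
                * seed_factor
                * (1.0 - E * inhib)
                * (1.0 - N / N_max)
            )
            N = N + config.dt * np.maximum(dN, 0.0)
            N = np.minimum(N, N_max)
            t += config.dt
            if not np.all(np.isfinite(N)):
                raise FloatingPointError(
                    f"non-finite neointimal state at t={t:.2f} days"
                )
        areas[:, day] = A0 - N
    days = np.arange(n_days, dtype=float)
    return LumenSeries(areas=areas, days=days)


def compute_acsa(ls: LumenSeries) -> np.ndarray:
    """Average cross-sectional lumen area per day (mm^2)."""
    return ls.areas.mean(axis=0)


def compute_mral(ls: LumenSeries) -> np.ndarray:
    """Maximum relative area loss per day: max_i (1 - A_i(t) / A_i(0))."""
    A0 = ls.initial
    if np.any(A0 == 0):
        raise ZeroDivisionError("zero initial slice area")
    rel_loss = 1.0 - ls.areas / A0[:, None]
    return rel_loss.max(axis=0)


def generate_dataset(
    space: ParameterSpace | None = None,
    n: int = 512,
    config: EmulatorConfig | None = None,
    seed: int = 0,
) -> Dataset:
    """Sobol design of ``n`` points with one emulator run per point.

    Per-run seeds are derived from the master seed and the row index through
    a seed sequence, so the dataset is bitwise reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = space or default_space()
    config = config or EmulatorConfig()
    samples = sobol_samples(space, n, scramble_seed=seed)
    run_seeds = np.random.SeedSequence(seed).spawn(n)
    acsa_rows, mral_rows = [], []
    for row, ss in zip(samples.values, run_seeds):
        ls = simulate(row, config, seed=np.random.default_rng(ss))
        acsa_rows.append(compute_acsa(ls))
        mral_rows.append(compute_mral(ls))
    days = np.arange(int(round(config.horizon)) + 1, dtype=float)
    return Dataset(
        samples=samples,
        acsa=np.asarray(acsa_rows),
        mral=np.asarray(mral_rows),
        days=days,
        provenance={
            "master_seed": int(seed),
            "config_digest": config.digest(),
            "config": config.to_dict(),
            "n": int(n),
        },
    )
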