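"""Uncertain-parameter space: bounds, unit-cube scaling and low-discrepancy sampling.

The study considers four independent, uniformly distributed inputs of the
restenosis model: the endothelium regeneration time (days), the maximum blood
flow velocity (m/s), the relative threshold strain for smooth-muscle-cell bond
breaking (dimensionless, expressed relative to a 30% pre-strained vessel) and
the fenestration percentage of the internal elastic lamina (%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SampleMatrix",
    "default_space",
    "scale_unit_to_physical",
    "scale_physical_to_unit",
    "sobol_samples",
    "uniform_cv",
    "rescale_strain",
]

#: Pre-strain of the pressurised vessel; stretch-test strains measured on
#: unstrained samples are re-expressed relative to this state.
PRE_STRAIN = 0.3

DEFAULT_NAMES = (
    "endothelium_regen_days",
    "flow_velocity_m_s",
    "threshold_strain",
    "fenestration_pct",
)
DEFAULT_MINS = (10.0, 0.133, 0.446, 2.0)
DEFAULT_MAXS = (20.0, 0.399, 0.785, 10.0)
DEFAULT_UNITS = ("day", "m/s", "-", "%")


@dataclass(frozen=True)
class ParameterSpace:
    """Axis-aligned box of independent uniform inputs."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        if mins.ndim != 1 or mins.shape != maxs.shape:
            raise ValueError("mins and maxs must be 1-D arrays of equal length")
        if len(self.names) != mins.size:
            raise ValueError("names length must match bounds")
        if not np.all(mins < maxs):
            bad = [self.names[i] for i in np.nonzero(~(mins < maxs))[0]]
            raise ValueError(f"min >= max for parameter(s): {bad}")

    @property
    def d(self) -> int:
        return self.mins.size

    @property
    def widths(self) -> np.ndarray:
        return self.maxs - self.mins

    def contains(self, x: np.ndarray, atol: float = 1e-12) -> bool:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return bool(
            np.all(x >= self.mins - atol) and np.all(x <= self.maxs + atol)
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "units": list(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(
            names=tuple(d["names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            units=tuple(d.get("units", ())),
        )


@dataclass(frozen=True)
class SampleMatrix:
    """An n x d design in physical units, with sampling provenance."""

    values: np.ndarray
    space: ParameterSpace
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != self.space.d:
            raise ValueError(f"expected n x {self.space.d} matrix, got {v.shape}")
        if not self.space.contains(v):
            raise ValueError("sample rows fall outside the parameter box")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def default_space() -> ParameterSpace:
    """The four-parameter uniform box of the restenosis study."""
    return ParameterSpace(
        names=DEFAULT_NAMES,
        mins=np.array(DEFAULT_MINS),
        maxs=np.array(DEFAULT_MAXS),
        units=DEFAULT_UNITS,
    )


def scale_unit_to_physical(u: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Affine map from the unit hypercube to the physical parameter box."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        flat = np.atleast_2d(u)
        bad = np.nonzero(np.any((flat < 0) | (flat > 1), axis=0))[0]
        names = [space.names[i] for i in bad if i < space.d]
        raise ValueError(f"unit-cube coordinates out of [0, 1] for: {names}")
    return space.mins + u * space.widths


def scale_physical_to_unit(x: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Inverse of :func:`scale_unit_to_physical`."""
    return (np.asarray(x, dtype=float) - space.mins) / space.widths


def sobol_samples(
    space: ParameterSpace,
    n: int,
    scramble_seed: int | None = 0,
) -> SampleMatrix:
    """Draw ``n`` points of a Sobol low-discrepancy sequence in the box.

    With ``scramble_seed`` set (the default) the sequence is Owen-scrambled
    and fully reproducible from the seed; replicated runs use distinct seeds.
    With ``scramble_seed=None`` the raw sequence is used and its degenerate
    all-zeros first point is skipped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scramble_seed is None:
        eng = qmc.Sobol(space.d, scramble=False)
        eng.fast_forward(1)  # drop the all-zeros corner point
        skip = 1
    else:
        eng = qmc.Sobol(space.d, scramble=True, seed=int(scramble_seed))
        skip = 0
    with warnings.catch_warnings():
        # arbitrary n is a legitimate request; balance is advisory here
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        u = eng.random(n)
    return SampleMatrix(
        values=scale_unit_to_physical(u, space),
        space=space,
        provenance={
            "sequence": "sobol",
            "scramble": scramble_seed is not None,
            "scramble_seed": scramble_seed,
            "skip": skip,
            "n": int(n),
        },
    )


def uniform_cv(lo: float, hi: float) -> float:
    """Coefficient of variation of a Uniform(lo, hi) distribution.

    CV = SD / mean = ((hi - lo) / sqrt(12)) / ((lo + hi) / 2).
    """
    if lo + hi == 0:
        raise ZeroDivisionError("CV undefined: Uniform(lo, hi) has zero mean")
    sd = (hi - lo) / np.sqrt(12.0)
    mean = 0.5 * (lo + hi)
    return float(sd / mean)


def rescale_strain(sigma_abso: float) -> float:
    """Re-express an absolute stretch-test strain relative to the pre-strained vessel.

    sigma_rela = (sigma_abso + 1) / (1 + PRE_STRAIN) - 1.
    """
    return float((sigma_abso + 1.0) / (1.0 + PRE_STRAIN) - 1.0)
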