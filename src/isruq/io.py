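"""Run configuration, seed derivation, and delimited-text / JSON artifact I/O.

All numeric payloads round-trip losslessly: CSV values are written with 17
significant digits (enough to reproduce any float64 bitwise) and arrays are
stored in NumPy's portable ``.npz`` container inside model archives.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emulator import Dataset, EmulatorConfig
from .params import ParameterSpace, SampleMatrix, default_space

__all__ = [
    "RunConfig",
    "read_config",
    "derive_seeds",
    "write_provenance",
    "write_dataset",
    "read_dataset",
    "write_uq_result",
    "write_sobol_result",
]

CSV_FLOAT_FORMAT = "%.17g"

_SCHEMA = {
    "space": {"names": list, "mins": list, "maxs": list, "units": list},
    "emulator": {f: (int, float) for f in EmulatorConfig.__dataclass_fields__},
    "surrogate": {
        "n_train": int, "n_snapshots": int, "energy_threshold": float,
        "folds": int, "cv_repetitions": int, "restarts": int,
    },
    "uq": {
        "n": int, "reps": int, "days": list, "restenosis_threshold": float,
    },
    "sensitivity": {"n": int, "reps": int},
    "seeds": {"master": int},
    "output_dir": str,
}

_DEFAULTS = {
    "surrogate": {"n_train": 512, "n_snapshots": 100,
                  "energy_threshold": 0.999, "folds": 4,
                  "cv_repetitions": 1, "restarts": 10},
    "uq": {"n": 100_000, "reps": 100, "days": [5, 10, 15, 20, 30],
           "restenosis_threshold": 0.5},
    "sensitivity": {"n": 4096, "reps": 10},
    "seeds": {"master": 0},
    "output_dir": "results",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of a full study run."""

    space: ParameterSpace
    emulator: EmulatorConfig
    surrogate: dict
    uq: dict
    sensitivity: dict
    master_seed: int
    output_dir: Path
    raw: dict = field(default_factory=dict, repr=False)


def _check_block(name: str, block: dict, schema: dict) -> None:
    unknown = set(block) - set(schema)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}' block: {sorted(unknown)}"
        )
    for key, typ in schema.items():
        if key in block and not isinstance(block[key], typ) and not (
            typ is float and isinstance(block[key], int)
        ):
            raise ConfigError(
                f"'{name}.{key}' must be of type {typ}, got "
                f"{type(block[key]).__name__}"
            )


def read_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run config; ``None`` gives defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for name in ("space", "emulator", "surrogate", "uq", "sensitivity", "seeds"):
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"'{name}' must be a mapping")
            _check_block(name, raw[name], _SCHEMA[name])

    space = (ParameterSpace.from_dict(raw["space"]) if "space" in raw
             else default_space())
    emulator = EmulatorConfig.from_dict(raw.get("emulator", {})) \
        if raw.get("emulator") else EmulatorConfig()

    def merged(name):
        out = dict(_DEFAULTS[name])
        out.update(raw.get(name, {}))
        return out

    return RunConfig(
        space=space,
        emulator=emulator,
        surrogate=merged("surrogate"),
        uq=merged("uq"),
        sensitivity=merged("sensitivity"),
        master_seed=int(merged("seeds")["master"]),
        output_dir=Path(raw.get("output_dir", _DEFAULTS["output_dir"])),
        raw=raw,
    )


#: Stage order for deterministic per-stage seed derivation.
_STAGES = ("dataset", "train", "cv", "uq", "sensitivity")


def derive_seeds(master_seed: int) -> dict:
    """Derive one 31-bit stage seed per pipeline stage from the master seed.

    Stage i receives the first state word of ``SeedSequence(master).spawn()``
    child i, reduced mod 2^31, in the fixed order dataset, train, cv, uq,
    sensitivity.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(c.generate_state(1)[0] % (2**31))
        for stage, c in zip(_STAGES, children)
    }


def write_provenance(directory: str | Path, config: RunConfig,
                     extra: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": {
            "space": config.space.to_dict(),
            "emulator": config.emulator.to_dict(),
            "surrogate": config.surrogate,
            "uq": config.uq,
            "sensitivity": config.sensitivity,
            "seeds": {"master": config.master_seed,
                      **derive_seeds(config.master_seed)},
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        payload.update(extra)
    # distinct from any dataset-level provenance.json in the same directory
    out = directory / "run_provenance.json"
    out.write_text(json.dumps(payload, indent=2))
    return out


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    try:
        # round_trip parsing: bitwise-exact recovery of %.17g floats
        return pd.read_csv(path, float_precision="round_trip", **kwargs)
    except Exception as exc:  # surface pandas' line-numbered message
        raise ValueError(f"failed to parse {path}: {exc}") from exc


def _day_columns(n_t: int) -> list[str]:
    return [f"day_{d:02d}" for d in range(n_t)]


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write samples.csv, qoi_acsa.csv, qoi_mral.csv and provenance.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        dataset.samples.values, columns=list(dataset.samples.space.names)
    ).to_csv(directory / "samples.csv", index=False,
             float_format=CSV_FLOAT_FORMAT)
    cols = _day_columns(dataset.n_t)
    for q in ("acsa", "mral"):
        pd.DataFrame(dataset.qoi(q), columns=cols).to_csv(
            directory / f"qoi_{q}.csv", index=False,
            float_format=CSV_FLOAT_FORMAT,
        )
    prov = {
        "dataset": dataset.provenance,
        "samples": dataset.samples.provenance,
        "space": dataset.samples.space.to_dict(),
    }
    (directory / "provenance.json").write_text(json.dumps(prov, indent=2))


def read_dataset(directory: str | Path) -> Dataset:
    directory = Path(directory)
    prov = json.loads((directory / "provenance.json").read_text())
    space = ParameterSpace.from_dict(prov["space"])
    samples_df = _read_csv(directory / "samples.csv")
    missing = set(space.names) - set(samples_df.columns)
    if missing:
        raise ValueError(f"samples.csv missing columns: {sorted(missing)}")
    qois = {}
    for q in ("acsa", "mral"):
        df = _read_csv(directory / f"qoi_{q}.csv", dtype=float)
        qois[q] = df.to_numpy(dtype=float)
    n_t = qois["acsa"].shape[1]
    return Dataset(
        samples=SampleMatrix(
            values=samples_df[list(space.names)].to_numpy(dtype=float),
            space=space,
            provenance=prov.get("samples", {}),
        ),
        acsa=qois["acsa"],
        mral=qois["mral"],
        days=np.arange(n_t, dtype=float),
        provenance=prov.get("dataset", {}),
    )


def write_uq_result(result, directory: str | Path) -> None:
    """Write uq_summary.csv (day x statistic), densities.json, restenosis.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = {"day": result.days.astype(int)}
    for q in result.mean:
        rows[f"{q}_mean"] = result.mean[q]
        rows[f"{q}_sd"] = result.sd[q]
        rows[f"{q}_cv_pct"] = 100.0 * result.cv[q]
        rows[f"{q}_rep_sd_of_mean"] = result.replicate_sd[q]["mean"]
        for c, (lo, hi) in result.bands[q].items():
            pct = int(round(100 * c))
            rows[f"{q}_p{pct}_lo"] = lo
            rows[f"{q}_p{pct}_hi"] = hi
    pd.DataFrame(rows).to_csv(directory / "uq_summary.csv", index=False,
                              float_format=CSV_FLOAT_FORMAT)
    pd.DataFrame({
        "day": result.days.astype(int),
        "restenosis_fraction": result.restenosis,
    }).to_csv(directory / "restenosis.csv", index=False,
              float_format=CSV_FLOAT_FORMAT)
    (directory / "densities.json").write_text(json.dumps({
        "threshold": result.restenosis_threshold,
        "n": result.n, "reps": result.reps,
        "densities": result.densities,
    }, indent=2))


def write_sobol_result(result, directory: str | Path, qoi: str) -> None:
    """Write sobol_first/total CSVs (rows = days, cols = parameters) + CIs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tag, values, ci in (
        ("first", result.first_order, result.first_ci),
        ("total", result.total_order, result.total_ci),
    ):
        df = pd.DataFrame(values, columns=list(result.names))
        df.insert(0, "day", result.days.astype(int))
        df.to_csv(directory / f"sobol_{tag}_{qoi}.csv", index=False,
                  float_format=CSV_FLOAT_FORMAT)
        if ci is not None:
            lo = pd.DataFrame(ci[:, :, 0], columns=[f"{n}_lo" for n in result.names])
            hi = pd.DataFrame(ci[:, :, 1], columns=[f"{n}_hi" for n in result.names])
            out = pd.concat(
                [pd.Series(result.days.astype(int), name="day"), lo, hi], axis=1
            )
            out.to_csv(directory / f"sobol_{tag}_{qoi}_ci.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)
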