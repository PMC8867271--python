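"""Shared fixtures: one desk-scale rerun of the full study design.

The pipeline fixture reproduces the study layout at the sizes used throughout
the analysis: a 512-run Sobol training design from the growth emulator,
a 100-snapshot POD at the 99.9% energy threshold with one GP per retained
coefficient, fourfold cross-validation, replicated 10^4-sample qMC
uncertainty estimation and 2^12-base Saltelli sensitivity analysis. It is
session-scoped because training dominates the suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from isruq import sensitivity as sens
from isruq import surrogate as surr
from isruq import uq as uqmod
from isruq.emulator import generate_dataset
from isruq.io import derive_seeds

MASTER_SEED = 0


@pytest.fixture(scope="session")
def seeds():
    return derive_seeds(MASTER_SEED)


@pytest.fixture(scope="session")
def dataset(seeds):
    """512-run emulator training dataset (the study's design size)."""
    return generate_dataset(n=512, seed=seeds["dataset"])


@pytest.fixture(scope="session")
def model(dataset, seeds):
    return surr.train(dataset, n_snapshots=100, energy_threshold=0.999,
                      seed=seeds["train"])


@pytest.fixture(scope="session")
def cv_report(dataset, seeds):
    return surr.cross_validate(dataset, folds=4, repetitions=1,
                               seed=seeds["cv"], n_snapshots=100)


@pytest.fixture(scope="session")
def uq_result(model, seeds):
    return uqmod.replicate_uq(model, n=10_000, reps=10,
                              master_seed=seeds["uq"])


@pytest.fixture(scope="session")
def sobol_acsa(model, seeds):
    def f(X):
        return surr.predict_qoi(model, X, qoi="acsa", monotone=True)

    return sens.sensitivity_over_time(
        f, model.space, n=2**12, reps=10, master_seed=seeds["sensitivity"]
    )


@pytest.fixture(scope="session")
def small_dataset(seeds):
    """Cheap 64-run dataset for tests that only need shapes and trends."""
    return generate_dataset(n=64, seed=seeds["dataset"] + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
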