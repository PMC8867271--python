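"""End-to-end surrogate: training, prediction, cross-validation, archiving."""

import numpy as np
import pytest

from isruq import surrogate as surr
from isruq.emulator import Dataset
from isruq.params import ParameterSpace, SampleMatrix, sobol_samples


def _synthetic_dataset(n=48, n_t=31, seed=0, linear=False):
    """Deterministic smooth low-rank map from inputs to decreasing series.

    With ``linear=True`` the varying part is a rank-one linear map of the
    inputs (exactly learnable by the GP); otherwise a smooth rank-three map.
    """
    space = ParameterSpace(
        names=("a", "b", "c", "d"),
        mins=np.zeros(4), maxs=np.ones(4),
    )
    samples = sobol_samples(space, n, scramble_seed=seed)
    X = samples.values
    t = np.linspace(0, 1, n_t)
    if linear:
        Y = 3.0 - np.outer(0.3 + X[:, 0] + 0.5 * X[:, 1], t)
    else:
        Y = (3.0 - 1.5 * np.outer(X[:, 0] + 0.5 * X[:, 1], t)
             - 0.3 * np.outer(np.sin(2 * X[:, 2]), t**2))
    mral = 1 - Y / Y[:, :1]
    return Dataset(samples=samples, acsa=Y, mral=np.clip(mral, 0, 0.99),
                   days=np.arange(n_t, dtype=float))


class TestTrain:
    def test_constant_response_collapses_to_rank_one(self):
        ds = _synthetic_dataset(n=24)
        const = np.full_like(ds.acsa, 2.5)
        ds2 = Dataset(samples=ds.samples, acsa=const, mral=ds.mral,
                      days=ds.days)
        model = surr.train(ds2, n_snapshots=20, seed=0, restarts=2,
                           qois=("acsa",))
        assert model.per_qoi["acsa"].basis.k == 1
        pred = surr.predict_qoi(model, ds.samples.values[:5], qoi="acsa")
        np.testing.assert_allclose(pred, 2.5, atol=1e-6)

    def test_study_design_trains_with_positive_ranks(self, model):
        for q in ("acsa", "mral"):
            assert model.per_qoi[q].basis.k >= 1
            assert len(model.per_qoi[q].gps) == model.per_qoi[q].basis.k

    def test_retraining_is_deterministic(self):
        ds = _synthetic_dataset(n=24)
        a = surr.train(ds, n_snapshots=16, seed=3, restarts=2)
        b = surr.train(ds, n_snapshots=16, seed=3, restarts=2)
        x = ds.samples.values[:4]
        np.testing.assert_array_equal(
            surr.predict_qoi(a, x, qoi="acsa"),
            surr.predict_qoi(b, x, qoi="acsa"),
        )


class TestPredict:
    def test_noise_free_interpolation(self):
        ds = _synthetic_dataset(n=40)
        # full-rank basis: no truncation error obscures the GP interpolation
        model = surr.train(ds, n_snapshots=40, energy_threshold=1.0, seed=0,
                           restarts=4, qois=("acsa",))
        pred = surr.predict_qoi(model, ds.samples.values, qoi="acsa")
        rel = np.linalg.norm(pred - ds.acsa, axis=1) / np.linalg.norm(
            ds.acsa, axis=1
        )
        assert rel.max() < 1e-3

    def test_variance_nonnegative(self, model):
        x = sobol_samples(model.space, 16, scramble_seed=9).values
        _, var = surr.predict_qoi(model, x, qoi="acsa", return_variance=True)
        assert np.all(var >= 0)

    def test_monotone_cleanup_on_sobol_points(self, model):
        x = sobol_samples(model.space, 100, scramble_seed=4).values
        acsa = surr.predict_qoi(model, x, qoi="acsa", monotone=True)
        mral = surr.predict_qoi(model, x, qoi="mral", monotone=True)
        assert np.all(np.diff(acsa, axis=1) <= 1e-10)
        assert np.all(np.diff(mral, axis=1) >= -1e-10)
        assert np.all((mral >= 0) & (mral < 1))

    def test_extrapolation_warns(self, model):
        x = model.space.maxs * 1.5
        with pytest.warns(UserWarning, match="extrapolat"):
            surr.predict_qoi(model, x, qoi="acsa")

    def test_heldout_correlation(self, dataset, seeds):
        """Predicted-vs-expected over all time steps clusters on the
        diagonal: Pearson r > 0.99 for the mean lumen area."""
        sub = Dataset(
            samples=SampleMatrix(values=dataset.samples.values[:384],
                                 space=dataset.samples.space),
            acsa=dataset.acsa[:384], mral=dataset.mral[:384],
            days=dataset.days,
        )
        m = surr.train(sub, n_snapshots=100, seed=seeds["train"])
        pred = surr.predict_qoi(m, dataset.samples.values[384:], qoi="acsa")
        truth = dataset.acsa[384:]
        r = np.corrcoef(pred.ravel(), truth.ravel())[0, 1]
        assert r > 0.99


class TestIsotonic:
    def test_projects_onto_monotone_cone(self):
        y = np.array([3.0, 2.0, 2.5, 1.0])
        out = surr.isotonic_cleanup(y, "non-increasing")
        assert np.all(np.diff(out) <= 1e-12)
        assert out[0] == 3.0 and out[-1] == 1.0

    def test_monotone_input_unchanged(self):
        y = np.array([0.0, 0.2, 0.2, 0.9])
        np.testing.assert_array_equal(
            surr.isotonic_cleanup(y, "non-decreasing"), y
        )

    def test_matches_sklearn_isotonic(self, rng):
        from sklearn.isotonic import IsotonicRegression

        y = rng.normal(size=40)
        ours = surr.isotonic_cleanup(y, "non-decreasing")
        ref = IsotonicRegression().fit_transform(np.arange(40), y)
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestSerialization:
    def test_round_trip_is_bitwise(self, model, tmp_path):
        model.save(tmp_path / "m")
        loaded = surr.SurrogateModel.load(tmp_path / "m")
        x = sobol_samples(model.space, 32, scramble_seed=1).values
        for q in ("acsa", "mral"):
            np.testing.assert_array_equal(
                surr.predict_qoi(model, x, qoi=q),
                surr.predict_qoi(loaded, x, qoi=q),
            )


class TestCrossValidation:
    def test_exactly_learnable_map(self):
        ds = _synthetic_dataset(n=48, linear=True)
        rep = surr.cross_validate(ds, folds=4, seed=0, n_snapshots=36,
                                  restarts=4, qois=("acsa",))
        assert rep.e_gp["acsa"] < 1e-3

    def test_gp_error_dominates_projection_error(self, cv_report):
        """The GP reconstruction cannot beat the projection of the truth
        onto the basis, up to rare statistical violations across folds."""
        for q in ("acsa", "mral"):
            e_pod = np.array(cv_report.per_fold[q]["e_pod"])
            e_gp = np.array(cv_report.per_fold[q]["e_gp"])
            violations = np.mean(e_gp < e_pod - 1e-12)
            assert violations <= 0.05

    def test_error_decreases_with_training_size(self, dataset, cv_report,
                                                seeds):
        small = Dataset(
            samples=SampleMatrix(values=dataset.samples.values[:64],
                                 space=dataset.samples.space),
            acsa=dataset.acsa[:64], mral=dataset.mral[:64], days=dataset.days,
        )
        rep64 = surr.cross_validate(small, folds=4, seed=seeds["cv"],
                                    n_snapshots=48)
        for q in ("acsa", "mral"):
            assert cv_report.e_gp[q] <= rep64.e_gp[q]

    def test_fold_validation(self):
        ds = _synthetic_dataset(n=6)
        with pytest.raises(ValueError):
            surr.cross_validate(ds, folds=7)
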