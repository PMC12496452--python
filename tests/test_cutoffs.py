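"""ROC construction, Youden optimization, and the response-surface model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import irtfit as it
from irtfit.cutoffs import PREDICTOR_SETS, _design


def brute_force_youden(null_v, alt_v):
    """Max of Se + Sp - 1 over every distinct observed value as threshold."""
    null_v, alt_v = np.asarray(null_v, float), np.asarray(alt_v, float)
    best = -1.0
    for t in np.unique(np.concatenate([null_v, alt_v])):
        se = (alt_v >= t - 1e-12).mean()
        sp = (null_v < t - 1e-12).mean()
        best = max(best, se + sp - 1)
    return best


class TestRocCurve:
    def test_separated_samples(self):
        roc = it.roc_curve([0.01, 0.02], [0.03, 0.04], step=0.001)
        inside = (roc.thresholds > 0.0205) & (roc.thresholds < 0.0305)
        assert inside.any()
        assert np.all(roc.sensitivity[inside] == 1.0)
        assert np.all(roc.specificity[inside] == 1.0)
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
        assert roc.sensitivity[-1] == 0.0 or roc.specificity[-1] == 1.0

    def test_monotone_sweep(self):
        rng = np.random.default_rng(0)
        roc = it.roc_curve(rng.gamma(2, 0.005, 200), rng.gamma(4, 0.01, 50))
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)
        assert np.all(np.diff(roc.specificity) >= -1e-12)
        assert np.all((roc.youden >= -1) & (roc.youden <= 1))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            it.roc_curve([], [0.1])


class TestYoudenOptimal:
    def test_perfect_separation(self):
        rec = it.youden_optimal(it.roc_curve([0.01, 0.02], [0.03, 0.04]))
        assert rec.max_j == pytest.approx(1.0)
        assert 0.02 < rec.recommended <= 0.0305
        assert rec.recommended == rec.optimal_interval[0]
        assert (rec.fp_rate, rec.tp_rate) == (0.0, 1.0)

    def test_interleaved_example_with_disjoint_optima(self):
        rec = it.youden_optimal(it.roc_curve([0.01, 0.03], [0.02, 0.04]))
        assert rec.max_j == pytest.approx(0.5)
        assert not rec.contiguous
        assert rec.recommended <= 0.02  # lowest optimal threshold wins

    @given(st.data())
    def test_equals_brute_force_search(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        # values on the 0.001 lattice so the grid visits every candidate
        null_v = rng.integers(0, 120, size=rng.integers(2, 40)) / 1000
        alt_v = rng.integers(20, 150, size=rng.integers(2, 20)) / 1000
        rec = it.youden_optimal(it.roc_curve(null_v, alt_v))
        assert rec.max_j == pytest.approx(brute_force_youden(null_v, alt_v), abs=1e-12)


class TestApplyCutoff:
    def test_degenerate_cutoffs(self):
        v = np.array([0.01, 0.05, 0.2])
        labels = np.array([False, False, True])
        assert it.apply_cutoff(v, labels, 0.0) == (1.0, 1.0)
        assert it.apply_cutoff(v, labels, np.inf) == (0.0, 0.0)

    def test_consistent_with_recommendation(self):
        rng = np.random.default_rng(2)
        null_v = rng.gamma(2, 0.004, 300)
        alt_v = rng.gamma(6, 0.01, 60)
        rec = it.youden_optimal(it.roc_curve(null_v, alt_v))
        rates = it.apply_cutoff(
            np.concatenate([null_v, alt_v]),
            np.concatenate([np.zeros(300, bool), np.ones(60, bool)]),
            rec.recommended,
        )
        assert rates.fp_rate == pytest.approx(rec.fp_rate, abs=1e-12)
        assert rates.tp_rate == pytest.approx(rec.tp_rate, abs=1e-12)


STUDY_LATTICE = [(N, n) for N in (500, 1000, 5000, 10_000, 20_000, 50_000)
                 for n in (20, 40, 100, 200, 400)]


class TestSurfaceModel:
    def _noiseless_points(self):
        return [
            (N, n, it.DEFAULT_SURFACE_MODEL.predict(N, n)) for N, n in STUDY_LATTICE
        ]

    def test_exact_recovery_from_noiseless_data(self):
        fit = it.fit_surface_model(self._noiseless_points(), model_id=4)
        for name, beta in it.DEFAULT_SURFACE_MODEL.coefficients.items():
            assert fit.coefficients[name] == pytest.approx(beta, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        points = [(N, n, z + rng.normal(0, 0.002)) for (N, n, z) in self._noiseless_points()]
        fit = it.fit_surface_model(points, model_id=2)
        X, z = _design(points, PREDICTOR_SETS[2])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        got = [fit.coefficients["intercept"]] + [
            fit.coefficients[name] for name in PREDICTOR_SETS[2]
        ]
        assert np.allclose(got, beta, atol=1e-8)

    def test_extra_predictor_never_decreases_r2(self):
        rng = np.random.default_rng(4)
        points = [(N, n, z + rng.normal(0, 0.003)) for (N, n, z) in self._noiseless_points()]
        r2 = [it.fit_surface_model(points, mid).r2 for mid in (1, 2, 4, 7)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_selection_recovers_generating_structure(self):
        # adjusted R^2 among nested supersets is noisy on any single draw,
        # so require the generating structure to win over repeated draws
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(30):
            points = [(N, n, z + rng.normal(0, 0.002)) for (N, n, z) in self._noiseless_points()]
            wins += it.select_surface_model(points).model_id == 4
        assert wins > 15

    def test_selection_is_argmax_of_adjusted_r2(self):
        rng = np.random.default_rng(6)
        points = [(N, n, z + rng.normal(0, 0.003)) for (N, n, z) in self._noiseless_points()]
        best = it.select_surface_model(points)
        all_fits = [it.fit_surface_model(points, mid) for mid in PREDICTOR_SETS]
        assert best.adj_r2 == max(f.adj_r2 for f in all_fits)

    def test_rank_deficiency_detected(self):
        points = [(1000, 50, 0.02)] * 12
        with pytest.raises(ValueError):
            it.fit_surface_model(points, model_id=4)


class TestPredictReferenceValue:
    @pytest.mark.parametrize(
        "N,n,expected",
        [(13_217, 132, 0.026), (5_000, 20, 0.010), (500, 100, 0.047)],
    )
    def test_published_model_predictions(self, N, n, expected):
        assert it.predict_reference_value(N, n).value == pytest.approx(expected, abs=1e-9)

    def test_monotone_over_studied_ranges(self):
        Ns = np.array([500, 1000, 5000, 10_000, 20_000, 50_000])
        ns = np.array([20, 40, 100, 200, 400])
        preds = np.array([[it.predict_reference_value(N, n).raw for n in ns] for N in Ns])
        assert np.all(np.diff(preds, axis=1) > 0)  # increasing in test length
        assert np.all(np.diff(preds, axis=0) < 0)  # decreasing in sample size

    def test_model_file_round_trip(self, tmp_path):
        it.DEFAULT_SURFACE_MODEL.save(tmp_path / "surface.json")
        back = it.SurfaceModel.load(tmp_path / "surface.json")
        assert back.coefficients == it.DEFAULT_SURFACE_MODEL.coefficients
        assert back.predict(13_217, 132) == it.DEFAULT_SURFACE_MODEL.predict(13_217, 132)

    def test_negative_prediction_floored(self):
        model = it.SurfaceModel(model_id=1, coefficients={"intercept": -1.0})
        with pytest.warns(RuntimeWarning):
            pred = it.predict_reference_value(1000, 50, model)
        assert pred.value == 0.0
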