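"""EM calibration: posteriors, likelihood, recovery, and covariance."""

import numpy as np
import pytest

import irtfit as it
from irtfit.calibrate import DegenerateItemError, marginal_loglik, param_covariance
from irtfit.data import MISSING


@pytest.fixture(scope="module")
def recovery_fit(grid81):
    """One parameter-recovery calibration shared by several checks."""
    rng = np.random.default_rng(42)
    true = it.sample_fitting_params(10, rng)
    resp = it.simulate_responses(true, 5000, rng)
    return true, resp, it.fit_2pl(resp, grid81)


class TestPosteriorOverGrid:
    def test_hand_bayes_three_point_grid(self, toy_grid3):
        resp = it.ResponseMatrix(np.array([[1]]))
        post = it.posterior_over_grid(resp, [it.ItemParams2PL(1, 0)], toy_grid3)
        # prior (0.25, 0.5, 0.25) times sigmoid(theta), normalized
        assert np.abs(post[0] - [0.134470710685, 0.5, 0.365529289315]).max() < 1e-10

    def test_all_missing_person_gets_prior(self, toy_grid3):
        resp = it.ResponseMatrix(np.array([[1], [MISSING]]))
        post = it.posterior_over_grid(resp, [it.ItemParams2PL(1, 0)], toy_grid3)
        assert np.allclose(post[1], toy_grid3.weights, atol=1e-15)

    def test_rows_sum_to_one(self, grid81):
        rng = np.random.default_rng(3)
        resp = it.simulate_responses(it.sample_fitting_params(8, rng), 50, rng)
        post = it.posterior_over_grid(resp, it.sample_fitting_params(8, rng), grid81)
        assert np.abs(post.sum(axis=1) - 1).max() < 1e-12

    def test_param_length_checked(self, toy_grid3):
        resp = it.ResponseMatrix(np.array([[1, 0]]))
        with pytest.raises(ValueError):
            it.posterior_over_grid(resp, [it.ItemParams2PL(1, 0)], toy_grid3)


class TestMarginalLoglik:
    def test_symmetric_single_response(self, toy_grid3):
        resp = it.ResponseMatrix(np.array([[1]]))
        ll = marginal_loglik(resp, [it.ItemParams2PL(1, 0)], toy_grid3)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_all_missing_person_contributes_zero(self, grid81):
        rng = np.random.default_rng(4)
        params = it.sample_fitting_params(5, rng)
        resp = it.simulate_responses(params, 30, rng)
        padded = it.ResponseMatrix(
            np.vstack([resp.data, np.full((1, 5), MISSING, dtype=np.int8)])
        )
        assert marginal_loglik(padded, params, grid81) == pytest.approx(
            marginal_loglik(resp, params, grid81), abs=1e-10
        )

    def test_missing_equals_skipped_likelihood_term(self, toy_grid3):
        # three persons, two items; second person misses item 2
        params = [it.ItemParams2PL(1.0, 0.0), it.ItemParams2PL(2.0, 0.5)]
        data = np.array([[1, 0], [0, MISSING], [1, 1]], dtype=np.int8)
        resp = it.ResponseMatrix(data)
        w, x = toy_grid3.weights, toy_grid3.points
        p1 = it.icc_2pl(params[0], x)
        p2 = it.icc_2pl(params[1], x)
        expected = (
            np.log((w * p1 * (1 - p2)).sum())
            + np.log((w * (1 - p1)).sum())  # item-2 term skipped
            + np.log((w * p1 * p2).sum())
        )
        assert marginal_loglik(resp, params, toy_grid3) == pytest.approx(expected, abs=1e-12)

    def test_higher_at_generating_params_than_perturbed(self, grid81):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(10):
            params = it.sample_fitting_params(6, rng)
            resp = it.simulate_responses(params, 400, rng)
            shifted = [it.ItemParams2PL(p.slope * 1.5, p.difficulty + 0.5) for p in params]
            diffs.append(
                marginal_loglik(resp, params, grid81) - marginal_loglik(resp, shifted, grid81)
            )
        assert np.mean(diffs) > 0


class TestFit2PL:
    def test_parameter_recovery(self, recovery_fit):
        true, _, res = recovery_fit
        a_true = np.array([p.slope for p in true])
        b_true = np.array([p.difficulty for p in true])
        assert res.converged
        assert np.sqrt(np.mean((res.slopes - a_true) ** 2)) < 0.1
        assert np.sqrt(np.mean((res.difficulties - b_true) ** 2)) < 0.1

    def test_loglik_nondecreasing(self, recovery_fit):
        _, _, res = recovery_fit
        assert np.all(np.diff(res.loglik_path) > -1e-8)

    def test_ascent_under_heavy_missingness(self, grid81):
        rng = np.random.default_rng(6)
        resp = it.simulate_responses(it.sample_fitting_params(6, rng), 300, rng)
        resp = it.impose_missingness(resp, 0.5, rng)
        res = it.fit_2pl(resp, grid81)
        assert np.all(np.diff(res.loglik_path) > -1e-8)

    def test_degenerate_item_raises(self, grid81):
        data = np.array([[1, 1], [1, 0], [1, 1]], dtype=np.int8)
        with pytest.raises(DegenerateItemError, match="item_1"):
            it.fit_2pl(it.ResponseMatrix(data), grid81)


def _fisher_information_by_enumeration(params, grid, N):
    """Exact per-pattern Fisher information of the marginal model, times N.

    Enumerates all response patterns of a short test, computes each pattern's
    probability under the model and its score by central differences of the
    marginal log-likelihood: an oracle independent of the analytic formulas.
    """
    n = len(params)
    patterns = [tuple((m >> i) & 1 for i in range(n)) for m in range(2**n)]
    a, c = np.array([p.slope for p in params]), np.array([p.intercept for p in params])
    x0 = np.empty(2 * n)
    x0[0::2], x0[1::2] = a, c
    info = np.zeros((2 * n, 2 * n))
    h = 1e-5
    for pat in patterns:
        resp = it.ResponseMatrix(np.array([pat], dtype=np.int8))
        f0 = marginal_loglik(resp, (a, c), grid)
        grad = np.empty(2 * n)
        for i in range(2 * n):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (
                marginal_loglik(resp, (xp[0::2], xp[1::2]), grid)
                - marginal_loglik(resp, (xm[0::2], xm[1::2]), grid)
            ) / (2 * h)
        info += np.exp(f0) * np.outer(grad, grad)
    return N * info


@pytest.fixture(scope="module")
def small_fit(grid81):
    rng = np.random.default_rng(7)
    true = [it.ItemParams2PL(1.0, 0.0), it.ItemParams2PL(1.5, -0.8), it.ItemParams2PL(0.7, 0.6)]
    resp = it.simulate_responses(true, 600, rng)
    return true, resp, it.fit_2pl(resp, grid81)


class TestParamCovariance:
    def test_symmetric(self, small_fit):
        _, resp, res = small_fit
        cov = param_covariance(resp, res)
        assert np.abs(cov - cov.T).max() < 1e-10

    def test_analytic_matches_numerical_hessian(self, small_fit):
        _, resp, res = small_fit
        cl = param_covariance(resp, res, method="louis")
        cn = param_covariance(resp, res, method="numerical")
        assert np.abs(cl - cn).max() < 1e-3 * np.abs(cn).max()

    def test_matches_fisher_information_oracle(self, grid81):
        rng = np.random.default_rng(8)
        true = [it.ItemParams2PL(1.0, 0.0), it.ItemParams2PL(1.4, -0.5), it.ItemParams2PL(0.8, 0.7)]
        N = 20000
        resp = it.simulate_responses(true, N, rng)
        res = it.fit_2pl(resp, grid81, tol=1e-5)
        cov = param_covariance(resp, res)
        oracle = np.linalg.inv(_fisher_information_by_enumeration(true, grid81, N))
        assert np.abs(np.diag(cov) - np.diag(oracle)).max() < 0.25 * np.diag(oracle).max()

    def test_variance_scales_inversely_with_n(self, grid81):
        rng = np.random.default_rng(9)
        true = it.sample_fitting_params(4, rng)
        covs = {}
        for N in (2000, 8000):
            resp = it.simulate_responses(true, N, rng)
            covs[N] = np.diag(param_covariance(resp, it.fit_2pl(resp, grid81)))
        ratio = covs[8000] / covs[2000]
        assert 0.12 < np.median(ratio) < 0.45
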