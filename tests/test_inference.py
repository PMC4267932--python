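"""The four post-selection decision rules."""

import numpy as np
import pytest
from scipy import stats

from funcqtl import inference, lasso


class TestSinglePTest:
    def test_bonferroni_arithmetic(self):
        # effect engineered so the raw p lands near 3e-4, then scaled by p_total
        x = np.array([0.0, 1.0] * 10)
        rng = np.random.default_rng(3)
        y = 0.9 * x + rng.normal(size=20) * 0.5
        raw = lasso.refit_ols_single(x, y)[3]
        out = inference.single_p_test(np.column_stack([x]), y, [0], p_total=153)
        assert out[0] == pytest.approx(min(1.0, raw * 153))

    def test_capped_at_one(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 50).astype(float)
        y = rng.normal(size=50)
        out = inference.single_p_test(np.column_stack([x]), y, [0], p_total=153)
        assert out[0] <= 1.0

    def test_empty_selection_empty_report(self):
        assert inference.single_p_test(np.zeros((10, 1)) + np.arange(10)[:, None], np.zeros(10), [], 100) == {}

    def test_null_familywise_error_controlled(self):
        # post-selection Bonferroni screen: any adjusted p <= 0.05 is rare
        # under the global null (selection bias makes this slightly
        # anti-conservative, hence the 0.07 margin)
        reps, hits = 60, 0
        for s in range(reps):
            rng = np.random.default_rng(500 + s)
            X = rng.integers(0, 2, size=(150, 50)).astype(float)
            y = rng.normal(size=150)
            fit = lasso.cv_lasso_fit(X, y, seed=s)
            adj = inference.single_p_test(X, y, fit.selected, p_total=50)
            if any(v <= 0.05 for v in adj.values()):
                hits += 1
        assert hits / reps <= 0.07 + 2.5 * np.sqrt(0.07 * 0.93 / reps)


@pytest.fixture(scope="module")
def strong_qtl_mst():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 2, size=(400, 30)).astype(float)
    y = 5.0 * X[:, 3] + rng.normal(size=400)
    return inference.multi_split_test(X, y, n_splits=40, seed=2), X, y


class TestMultiSplitTest:
    def test_strong_qtl_detected(self, strong_qtl_mst):
        agg, _, _ = strong_qtl_mst
        assert agg[3] < 0.01

    def test_never_selected_markers_get_one(self, strong_qtl_mst):
        agg, _, _ = strong_qtl_mst
        # with one dominant QTL most null markers are never selected
        assert np.sum(agg == 1.0) >= 20

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            inference.multi_split_test(rng.normal(size=(10, 3)), rng.normal(size=10))

    def test_aggregation_rule_hand_check(self):
        # one marker, constant p across splits: Q(gamma) = p/gamma minimised
        # at gamma = 1, scaled by 1 - log(0.05)
        p_matrix = np.full((50, 1), 0.01)
        agg = inference._aggregate_split_pvalues(p_matrix)
        assert agg[0] == pytest.approx(min(1.0, (1 - np.log(0.05)) * 0.01), rel=1e-6)
        assert inference._aggregate_split_pvalues(np.ones((50, 1)))[0] == 1.0


class TestCovarianceTest:
    def test_zero_response_empty_report(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(30, 3))
        path = lasso.lasso_path(X, np.zeros(30))
        rep = inference.covariance_test(path, X, np.zeros(30), sigma_sq=1.0)
        assert rep.empty

    def test_p_is_exp_minus_T(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + rng.normal(size=60)
        path = lasso.lasso_path(X, y)
        rep = inference.covariance_test(path, X, y, sigma_sq=1.0)
        np.testing.assert_allclose(rep["p"], np.exp(-np.maximum(rep["T"], 0)))

    def test_statistics_match_grid_oracle(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(22)
        X = rng.normal(size=(40, 3))
        y = 1.2 * X[:, 1] + rng.normal(size=40)
        path = lasso.lasso_path(X, y)
        rep = inference.covariance_test(path, X, y, sigma_sq=1.0)

        Xs = (X - path.x_mean) / path.x_scale
        yc = y - path.y_mean
        n = 40

        def dense_coef(cols, lam):
            if not cols:
                return np.zeros(3)
            b = np.zeros(3)
            if lam <= 1e-12:
                b[cols] = np.linalg.lstsq(Xs[:, cols], yc, rcond=None)[0]
                return b
            m = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-14, max_iter=500000)
            m.fit(Xs[:, cols], yc)
            b[cols] = m.coef_
            return b

        # recompute each entry's statistic from dense coordinate-descent fits
        entries = 0
        for k in range(1, len(path.lambdas)):
            prev, cur = path.active_sets[k - 1], path.active_sets[k]
            if len(cur) <= len(prev):
                continue
            lam_next = float(path.lambdas[k])
            b_full = dense_coef(list(range(3)), lam_next)
            b_restr = dense_coef(prev, lam_next)
            T_oracle = yc @ (Xs @ b_full) - yc @ (Xs @ b_restr)
            assert rep["T"].iloc[entries] == pytest.approx(T_oracle, abs=1e-4)
            entries += 1
        assert entries == len(rep)

    def test_first_entry_null_distribution_quick(self):
        # orthonormal global null: T1 approximately Exp(1); a quick 400-rep
        # check (the full-depth calibration lives in the acceptance suite)
        rng = np.random.default_rng(23)
        n, p = 300, 80
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        T1 = []
        for _ in range(400):
            y = rng.normal(size=n)
            path = lasso.lasso_path(Q, y, standardize=False, fit_intercept=False, max_knots=3)
            rep = inference.covariance_test(path, Q, y, sigma_sq=1.0, max_entries=1)
            T1.append(rep["T"].iloc[0])
        assert stats.kstest(T1, "expon").pvalue > 0.005

    def test_nonpositive_sigma_rejected(self):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        path = lasso.lasso_path(X, y)
        with pytest.raises(ValueError):
            inference.covariance_test(path, X, y, sigma_sq=0.0)


class TestStabilitySelection:
    def test_single_subsample_binary_ssp(self):
        rng = np.random.default_rng(30)
        X = rng.integers(0, 2, size=(60, 20)).astype(float)
        y = rng.normal(size=60)
        ssp = inference.stability_selection(
            X, y, inference.SSPConfig(n_subsamples=1, q_target=5), seed=4
        )
        assert set(np.unique(ssp)) <= {0.0, 1.0}
        assert ssp.sum() == 5  # active set of exactly the target size here

    def test_strong_marker_always_selected(self):
        rng = np.random.default_rng(31)
        X = rng.integers(0, 2, size=(400, 50)).astype(float)
        y = 10.0 * X[:, 7] + rng.normal(size=400)
        ssp = inference.stability_selection(
            X, y, inference.SSPConfig(n_subsamples=100, q_target=10), seed=5
        )
        assert ssp[7] >= 0.99

    def test_null_mean_ssp_near_q_over_p(self):
        rng = np.random.default_rng(32)
        X = rng.integers(0, 2, size=(200, 100)).astype(float)
        y = rng.normal(size=200)
        ssp = inference.stability_selection(
            X, y, inference.SSPConfig(n_subsamples=200, q_target=10), seed=6
        )
        assert ssp.mean() == pytest.approx(0.10, abs=0.03)

    def test_subsample_indices_exposed(self):
        rng = np.random.default_rng(33)
        X = rng.integers(0, 2, size=(40, 10)).astype(float)
        y = rng.normal(size=40)
        ssp, idx = inference.stability_selection(
            X, y, inference.SSPConfig(n_subsamples=3, q_target=2), seed=7, return_indices=True
        )
        assert len(idx) == 3 and all(len(i) == 20 for i in idx)

    def test_q_exceeding_p_rejected(self):
        rng = np.random.default_rng(34)
        with pytest.raises(ValueError):
            inference.stability_selection(
                rng.normal(size=(40, 5)), rng.normal(size=40),
                inference.SSPConfig(q_target=10),
            )


class TestSSPThreshold:
    @pytest.mark.parametrize(
        "p,ev,expected",
        [(153, 1.0, 0.83), (153, 2.0, 0.66), (319, 1.0, 0.66), (319, 2.0, 0.58)],
    )
    def test_printed_threshold_calibration(self, p, ev, expected):
        assert inference.ssp_threshold(p, 10.0, ev) == expected

    def test_boundary_pi_equals_one(self):
        # E(V) = q^2/p puts the threshold exactly at 1
        assert inference.ssp_threshold(100, 10.0, 1.0) == 1.0

    def test_infeasible_threshold_rejected(self):
        with pytest.raises(ValueError):
            inference.ssp_threshold(100, 10.0, 0.5)  # pi > 1
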