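"""Bayesian mixed model: moments, PIP/BFDR rules, sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcqtl import blmm, synthetic


class TestMarginalMoments:
    def test_variance_plug_in(self):
        assert blmm.marginal_moments(np.eye(2), 1.0, 0.0) == pytest.approx(2.0)

    def test_covariance_plug_in(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert blmm.marginal_moments(S, 1.0, 1.0, 2.0) == pytest.approx(4.5)

    def test_monte_carlo_agreement(self):
        gm, _ = synthetic.simulate_pedigree_genotypes(8000, [], unmapped_count=1, seed=40)
        S = np.array([[1.5, -0.2], [-0.2, 0.4]])
        params = synthetic.TrueModelParams(
            0.0, 0.0, S, 0.8, np.zeros(1), np.zeros(1),
            np.array([-2.0, 1.0]), missing_rate=0.0, seed=41,
        )
        phen, _ = synthetic.simulate_longitudinal_traits(gm, params)
        wide = phen.pivot(index="individual_id", columns="time", values="value")
        assert np.var(wide[-2.0]) == pytest.approx(
            blmm.marginal_moments(S, 0.8, -2.0), rel=0.08
        )
        assert np.cov(wide[-2.0], wide[1.0])[0, 1] == pytest.approx(
            blmm.marginal_moments(S, 0.8, -2.0, 1.0), abs=0.15
        )


class TestPIPAndBFDR:
    def test_pip_arithmetic(self):
        pip, lfdr = blmm.compute_pip(np.array([[1], [1], [0], [1]]))
        assert pip[0] == pytest.approx(0.75)
        assert lfdr[0] == pytest.approx(0.25)

    def test_all_zero_draws(self):
        pip, _ = blmm.compute_pip(np.zeros((10, 3)))
        np.testing.assert_array_equal(pip, 0.0)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            blmm.compute_pip(np.empty((0, 3)))

    def test_bfdr_hand_arithmetic(self):
        sel, bfdr = blmm.bfdr_select(np.array([0.01, 0.02, 0.10, 0.30]), alpha=0.05)
        np.testing.assert_array_equal(sel, [0, 1, 2])
        assert bfdr == pytest.approx((0.01 + 0.02 + 0.10) / 3)

    def test_all_one_empty_selection(self):
        sel, bfdr = blmm.bfdr_select(np.ones(5))
        assert sel.size == 0 and np.isnan(bfdr)

    def test_all_zero_full_selection(self):
        sel, bfdr = blmm.bfdr_select(np.zeros(5))
        assert sel.size == 5 and bfdr == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        st.floats(0.01, 0.5),
    )
    def test_selection_rule_monotone(self, lfdrs, alpha):
        lfdrs = np.asarray(lfdrs)
        sel, bfdr = blmm.bfdr_select(lfdrs, alpha)
        # prefix means are non-decreasing after the minimum; a stricter
        # alpha never adds markers
        sel2, _ = blmm.bfdr_select(lfdrs, alpha / 2)
        assert set(sel2) <= set(sel)
        if sel.size:
            assert bfdr < alpha
            # selected markers have the smallest LFDRs
            assert lfdrs[sel].max() <= np.min(
                lfdrs[np.setdiff1d(np.arange(lfdrs.size), sel)], initial=1.0
            ) + 1e-12


def _simulate(n, p, beta=None, gamma=None, Sigma=None, s0=1.0, seed=0,
              missing=0.0, time_grid=None, alpha1=-1.0):
    gm, _ = synthetic.simulate_pedigree_genotypes(n, [], unmapped_count=p, seed=seed)
    params = synthetic.TrueModelParams(
        alpha0=10.0,
        alpha1=alpha1,
        Sigma=np.diag([4.0, 0.25]) if Sigma is None else Sigma,
        sigma0_sq=s0,
        beta=np.zeros(p) if beta is None else beta,
        gamma=np.zeros(p) if gamma is None else gamma,
        time_grid=np.arange(-4.0, 5.0) if time_grid is None else time_grid,
        missing_rate=missing,
        seed=seed + 1,
    )
    phen, truth = synthetic.simulate_longitudinal_traits(gm, params)
    return gm, phen, truth


class TestGibbsSampler:
    def test_degenerate_chain_config_rejected(self, small_genotypes):
        phen = pd.DataFrame(
            {
                "individual_id": small_genotypes.individuals[:5] * 2,
                "trait_id": "EP",
                "time": [0.0] * 5 + [1.0] * 5,
                "value": np.arange(10.0),
            }
        )
        with pytest.raises(ValueError, match="burn_in"):
            blmm.gibbs_sampler(phen, small_genotypes, n_iter=100, burn_in=100)

    def test_unknown_individuals_rejected(self, small_genotypes):
        phen = pd.DataFrame(
            {"individual_id": ["nobody"], "trait_id": "EP", "time": [0.0], "value": [1.0]}
        )
        with pytest.raises(ValueError, match="absent"):
            blmm.gibbs_sampler(phen, small_genotypes, n_iter=10, burn_in=5)

    def test_zero_qtl_calibration(self):
        gm, phen, _ = _simulate(200, 30, seed=50)
        _, summ = blmm.gibbs_sampler(phen, gm, n_iter=1000, burn_in=400, seed=51)
        m = summ.markers
        # variance components recovered, and PIPs stay low without signal
        assert summ.Sigma[0, 0] == pytest.approx(4.0, rel=0.25)
        assert summ.Sigma[1, 1] == pytest.approx(0.25, rel=0.25)
        assert summ.sigma0_sq == pytest.approx(1.0, rel=0.2)
        assert np.mean(m.pip_intercept < 0.5) >= 0.95
        assert np.mean(m.pip_slope < 0.5) >= 0.95

    def test_single_intercept_qtl_recovery(self):
        beta = np.zeros(60)
        beta[11] = 2.0  # one intercept sd
        gm, phen, _ = _simulate(300, 60, beta=beta, seed=52, missing=0.05)
        _, summ = blmm.gibbs_sampler(phen, gm, n_iter=1200, burn_in=400, seed=53)
        m = summ.markers
        assert m.pip_intercept[11] >= 0.9
        cond_eff = m.effect_intercept[11] / max(m.pip_intercept[11], 1e-9)
        assert cond_eff == pytest.approx(2.0, rel=0.25)

    def test_chains_agree_across_seeds(self):
        beta = np.zeros(20)
        beta[3] = 2.0
        gm, phen, _ = _simulate(150, 20, beta=beta, seed=54)
        _, s1 = blmm.gibbs_sampler(phen, gm, n_iter=2500, burn_in=1000, seed=1)
        _, s2 = blmm.gibbs_sampler(phen, gm, n_iter=2500, burn_in=1000, seed=2)
        d = np.abs(s1.markers.pip_intercept - s2.markers.pip_intercept)
        assert np.median(d) <= 0.05
        assert d.max() <= 0.2
        assert s1.markers.pip_intercept[3] >= 0.9 and s2.markers.pip_intercept[3] >= 0.9

    def test_seeded_reproducibility(self):
        gm, phen, _ = _simulate(60, 10, seed=55)
        d1, s1 = blmm.gibbs_sampler(phen, gm, n_iter=200, burn_in=100, seed=9)
        d2, s2 = blmm.gibbs_sampler(phen, gm, n_iter=200, burn_in=100, seed=9)
        np.testing.assert_array_equal(d1["beta"], d2["beta"])
        assert s1.sigma0_sq == s2.sigma0_sq


class TestReducedModel:
    def test_too_many_time_points_redirected(self):
        gm, phen, _ = _simulate(50, 5, seed=60)
        with pytest.raises(ValueError, match="full model"):
            blmm.reduced_model_sampler(phen, gm, n_iter=10, burn_in=5)

    def test_noiseless_repeats_put_variance_in_intercepts(self):
        gm, phen, _ = _simulate(
            100, 0, Sigma=np.diag([4.0, 0.0]), s0=1e-8, seed=61,
            time_grid=np.array([-0.5, 0.5]), alpha1=0.0,
        )
        summ = blmm.reduced_model_sampler(phen, gm, n_iter=600, burn_in=200, seed=62)
        assert summ.sigma0_sq < 0.05
        assert summ.Sigma[0, 0] == pytest.approx(4.0, rel=0.4)

    def test_no_markers_posterior_mean_is_grand_mean(self):
        gm, phen, _ = _simulate(
            120, 0, Sigma=np.diag([1.0, 0.0]), s0=0.5, seed=63,
            time_grid=np.array([-0.5, 0.5]),
        )
        summ = blmm.reduced_model_sampler(phen, gm, n_iter=800, burn_in=300, seed=64)
        a_draws = summ.diagnostics["alpha0_draws"]
        mc_se = a_draws.std() / np.sqrt(len(a_draws) / 10)  # crude IACT allowance
        assert abs(summ.alpha0 - phen["value"].mean()) <= max(2 * mc_se, 0.05)

    def test_ga_like_qtl_recovery(self):
        beta = np.zeros(40)
        beta[8] = 0.75  # about 0.5 sd of the intercept spread
        gm, phen, _ = _simulate(
            450, 40, beta=beta, Sigma=np.diag([2.25, 0.0]), s0=0.5, seed=65,
            time_grid=np.array([-0.5, 0.5]),
        )
        summ = blmm.reduced_model_sampler(phen, gm, n_iter=1000, burn_in=400, seed=66)
        assert summ.markers.pip_intercept[8] >= 0.9


def _naive_quadrature_sampler(y, ind, x, n_iter, burn_in, seed, w=0.5, a=0.1, b=0.1):
    """Independent oracle for the reduced model: same posterior, but the
    (r_j, beta_j) update integrates beta_j by numerical quadrature and
    conditions on the current random intercepts."""
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    p = x.shape[1]
    n_obs = y.size
    m_i = np.bincount(ind, minlength=n).astype(float)
    grid = np.linspace(-6, 6, 2001)

    alpha0 = y.mean()
    a0 = np.zeros(n)
    tau_sq, sigma0_sq = 1.0, 1.0
    beta = np.zeros(p)
    sv = np.ones(p)
    r = np.zeros(p, dtype=int)
    r_draws = []
    for it in range(n_iter):
        resid = y - alpha0 - a0[ind] - x[ind] @ beta
        alpha0 += resid.mean() + rng.normal(0, np.sqrt(sigma0_sq / n_obs))
        resid = y - alpha0 - a0[ind] - x[ind] @ beta
        c0 = np.bincount(ind, weights=resid + a0[ind], minlength=n) / sigma0_sq
        prec = m_i / sigma0_sq + 1.0 / tau_sq
        a0 = c0 / prec + rng.standard_normal(n) / np.sqrt(prec)
        resid = y - alpha0 - a0[ind] - x[ind] @ beta
        tau_sq = (0.5 * 1.0 + 0.5 * a0 @ a0) / rng.gamma(0.5 * 1.0 + n / 2)
        sigma0_sq = max(float(resid @ resid) / rng.chisquare(n_obs), 1e-12)
        for j in range(p):
            z = x[ind, j]
            part = resid + z * beta[j]
            # log-likelihood over the beta grid, spike handled separately
            ll = -0.5 * np.sum((part[:, None] - z[:, None] * grid[None, :]) ** 2, axis=0) / sigma0_sq
            prior = -0.5 * grid**2 / sv[j] - 0.5 * np.log(2 * np.pi * sv[j])
            joint = ll + prior
            mx = joint.max()
            slab_marg = np.trapezoid(np.exp(joint - mx), grid)
            log_slab = mx + np.log(slab_marg)
            log_spike = -0.5 * np.sum(part**2) / sigma0_sq
            logit = np.log(w / (1 - w)) + log_slab - log_spike
            if rng.random() < 1 / (1 + np.exp(-np.clip(logit, -700, 700))):
                r[j] = 1
                dens = np.exp(joint - joint.max())
                cdf = np.cumsum(dens)
                cdf /= cdf[-1]
                beta[j] = float(np.interp(rng.random(), cdf, grid))
                sv[j] = (b + 0.5 * beta[j] ** 2) / rng.gamma(a + 0.5)
            else:
                r[j] = 0
                beta[j] = 0.0
                sv[j] = b / rng.gamma(a)
            resid = part - z * beta[j]
        if it >= burn_in:
            r_draws.append(r.copy())
    return np.asarray(r_draws).mean(axis=0)


class TestOracleEquivalence:
    def test_collapsed_sampler_matches_quadrature_oracle(self):
        # 20-observation fixture: 10 individuals x 2 repeats, 2 markers
        rng = np.random.default_rng(70)
        n, p = 10, 2
        x = rng.integers(0, 2, size=(n, p)).astype(float)
        ind = np.repeat(np.arange(n), 2)
        a_true = rng.normal(0, 0.5, n)
        y = 1.0 + a_true[ind] + 1.2 * x[ind, 0] + rng.normal(0, 0.5, 2 * n)

        gm = synthetic.GenotypeMatrix(
            [f"I{i}" for i in range(n)],
            pd.DataFrame(
                {"marker_id": ["m0", "m1"], "linkage_group": "u", "position_cm": np.nan}
            ),
            x,
        )
        phen = pd.DataFrame(
            {
                "individual_id": [f"I{i}" for i in ind],
                "trait_id": "t",
                "time": np.tile([0.0, 1.0], n),
                "value": y,
            }
        )
        summ = blmm.reduced_model_sampler(phen, gm, n_iter=12000, burn_in=2000, seed=71)
        pip_pkg = summ.markers.pip_intercept.to_numpy()
        pip_oracle = _naive_quadrature_sampler(y, ind, x, 12000, 2000, seed=72)
        np.testing.assert_allclose(pip_pkg, pip_oracle, atol=0.03)
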