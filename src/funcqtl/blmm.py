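"""Bayesian linear mixed model with spike-and-slab marker priors.

The one-step model fits population trends, individual random
intercepts/slopes and sparse marker effects simultaneously:

    y_ik = a0 + a1 t_ik + alpha_i0 + alpha_i1 t_ik
           + sum_j x_ij beta_j + sum_j x_ij t_ik gamma_j + eps_ik,

with eps ~ N(0, sigma0^2), (alpha_i0, alpha_i1) ~ MVN(0, Sigma), flat
priors on (a0, a1), Jeffreys on sigma0^2, Sigma ~ Inv-Wishart(Psi, upsilon)
and, per marker effect, the mixture prior

    beta_j | r_j ~ (1 - r_j) I{beta_j = 0} + r_j N(0, sigma_j^2),

with r_j ~ Bernoulli(w) and sigma_j^2 ~ Inv-Gamma(a, b).  Intercept and
slope effects of the same marker carry independent indicators.

Estimation is by a partially collapsed Gibbs sampler.  Marker effects and
individual random effects both live on the individual level, so updates of
(r_j, beta_j) that condition on the current random effects mix very
poorly — a marker that happens to absorb part of the between-individual
variance can stay included almost permanently.  The sampler therefore
integrates the random effects *and* the candidate effect out analytically
when sampling each inclusion indicator (the marginal likelihood is
Gaussian with per-individual covariance sigma0^2 I + W_i Sigma W_i^T,
handled through 2x2 Woodbury identities), draws the effect from its
Gaussian conditional when included, and only afterwards imputes the random
effects from their exact full conditional, followed by the Sigma and
sigma0^2 conditionals.  Posterior inclusion probabilities (PIP), local
false discovery rates (LFDR = 1 - PIP) and the sorted prefix-mean BFDR
rule provide marker selection.

Traits observed at only two or three time points use the reduced model
(random intercepts only, no slope effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .synthetic import GenotypeMatrix

__all__ = [
    "BLMMPriors",
    "PosteriorSummary",
    "gibbs_sampler",
    "reduced_model_sampler",
    "marginal_moments",
    "compute_pip",
    "bfdr_select",
]


@dataclass
class BLMMPriors:
    w: float = 0.5
    a: float = 0.1
    b: float = 0.1
    Psi: np.ndarray = field(default_factory=lambda: np.eye(2))
    upsilon: float = 1.0

    def __post_init__(self) -> None:
        self.Psi = np.asarray(self.Psi, dtype=float)
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if not 0 < self.w < 1:
            raise ValueError("w must lie in (0, 1)")
        if np.any(np.linalg.eigvalsh(self.Psi) <= 0):
            raise ValueError("Psi must be positive-definite")


@dataclass
class PosteriorSummary:
    """Posterior marker table plus variance-component summaries."""

    markers: pd.DataFrame  # pip/lfdr/effect per marker (intercept, slope)
    alpha0: float
    alpha1: float
    Sigma: np.ndarray
    sigma0_sq: float
    diagnostics: dict


def marginal_moments(Sigma, sigma0_sq: float, t_k: float, t_h: float | None = None) -> float:
    """Marginal variance/covariance of observations under the mixed model.

    Var(y_ik) = sigma0^2 + S11 + 2 t S12 + t^2 S22;
    Cov(y_ik, y_ih) = S11 + (t_k + t_h) S12 + t_k t_h S22 for k != h.
    """
    S = np.asarray(Sigma, dtype=float)
    if t_h is None or t_h == t_k:
        return float(sigma0_sq + S[0, 0] + 2 * t_k * S[0, 1] + t_k**2 * S[1, 1])
    return float(S[0, 0] + (t_k + t_h) * S[0, 1] + t_k * t_h * S[1, 1])


def compute_pip(indicator_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities and LFDR = 1 - PIP from retained
    indicator draws (iterations x markers)."""
    draws = np.asarray(indicator_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty retained chain")
    pip = draws.mean(axis=0)
    return pip, 1.0 - pip


def bfdr_select(lfdrs: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Sorted prefix-mean Bayesian FDR selection.

    LFDRs are sorted ascending; the selected set is the largest prefix
    whose mean LFDR is still below ``alpha``; that mean is the reported
    set-level BFDR (NaN for an empty selection).
    """
    lfdrs = np.asarray(lfdrs, dtype=float)
    if np.any((lfdrs < 0) | (lfdrs > 1)):
        raise ValueError("LFDRs must lie in [0, 1]")
    order = np.argsort(lfdrs, kind="stable")
    prefix_means = np.cumsum(lfdrs[order]) / np.arange(1, lfdrs.size + 1)
    ok = np.nonzero(prefix_means < alpha)[0]
    if ok.size == 0:
        return np.asarray([], dtype=int), float("nan")
    T = int(ok[-1]) + 1
    return np.sort(order[:T]), float(prefix_means[T - 1])


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return float(scale / rng.gamma(shape))


def _prepare_observations(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix):
    ind_lookup = {ind: i for i, ind in enumerate(genotypes.individuals)}
    missing = set(phenotypes["individual_id"]) - set(ind_lookup)
    if missing:
        raise ValueError(f"{len(missing)} phenotype individuals absent from genotypes")
    ind = phenotypes["individual_id"].map(ind_lookup).to_numpy(dtype=int)
    t = phenotypes["time"].to_numpy(dtype=float)
    y = phenotypes["value"].to_numpy(dtype=float)
    x = genotypes.codes.copy()
    if np.isnan(x).any():  # mean-impute sparse missing genotype scores
        col_mean = np.nanmean(x, axis=0)
        nr, nc = np.nonzero(np.isnan(x))
        x[nr, nc] = col_mean[nc]
    return ind, t, y, x


def gibbs_sampler(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    priors: BLMMPriors | None = None,
    n_iter: int = 20000,
    burn_in: int = 10000,
    seed: int = 0,
    thin: int = 1,
) -> tuple[dict, PosteriorSummary]:
    """Partially collapsed Gibbs sampler for the full random-intercept/
    slope model.

    Scan order per iteration: each marker's (indicator, intercept effect)
    then (indicator, slope effect) with the random effects and the effect
    integrated out; slab variances; fixed effects (a0, a1) by the
    analogous collapsed Gaussian draw; the per-individual random effects
    from their exact bivariate Gaussian conditional; Sigma from its
    inverse-Wishart conditional; sigma0^2 from its scaled
    inverse-chi-square conditional under Jeffreys.  Missing (individual,
    time) cells are simply absent from the table and drop out of all
    likelihood sums.  Returns the retained draws and a posterior summary.
    """
    priors = priors or BLMMPriors()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter (empty retained chain)")
    ind, t, y, x = _prepare_observations(phenotypes, genotypes)
    n, p = x.shape
    if n < 2:
        raise ValueError("at least two individuals are required")
    n_obs = y.size
    rng = np.random.default_rng(seed)
    w = priors.w
    log_prior_odds = np.log(w / (1.0 - w))

    Zb = x[ind]
    Zg = Zb * t[:, None]
    W = np.column_stack([np.ones(n_obs), t])

    # per-individual cross-products of the trend design (fixed over the run)
    m_i = np.bincount(ind, minlength=n).astype(float)
    st_i = np.bincount(ind, weights=t, minlength=n)
    stt_i = np.bincount(ind, weights=t * t, minlength=n)
    x_sq = x * x

    coef0 = np.linalg.lstsq(W, y, rcond=None)[0]
    alpha = coef0.copy()
    a_re = np.zeros((n, 2))
    Sigma = np.eye(2)
    beta = np.zeros(p)
    gamma = np.zeros(p)
    r_b = np.zeros(p, dtype=int)
    r_g = np.zeros(p, dtype=int)
    sv_b = np.ones(p)
    sv_g = np.ones(p)
    resid0 = y - W @ alpha
    sigma0_sq = max(float(resid0 @ resid0 / max(n_obs - 2, 1)), 1e-6)

    draws = {
        "alpha0": [], "alpha1": [], "Sigma": [], "sigma0_sq": [],
        "beta": [], "gamma": [], "r_beta": [], "r_gamma": [],
    }
    pd_resamples = 0

    def spike_slab_sweep(r_flags, effects, slab_vars, which, state):
        """One sweep over the markers for intercept ('b') or slope ('g')
        effects, with random effects integrated out.

        ``state`` carries (b0, b1): per-individual W_i^T r_i of the
        residual y - W alpha - X*effects (random effects excluded),
        updated in place, plus the Woodbury arrays of this iteration.
        """
        b0, b1, Minv00, Minv01, Minv11, g_int, g_slo = state
        if which == "b":
            u0, u1, gz = m_i, st_i, g_int
        else:
            u0, u1, gz = st_i, stt_i, g_slo
        for j in range(p):
            xj = x[:, j]
            if effects[j] != 0.0:
                b0 += xj * m_i * effects[j] if which == "b" else xj * st_i * effects[j]
                b1 += xj * st_i * effects[j] if which == "b" else xj * stt_i * effects[j]
            # z^T V^{-1} r and z^T V^{-1} z through the 2x2 Woodbury blocks
            t0 = Minv00 * b0 + Minv01 * b1
            t1 = Minv01 * b0 + Minv11 * b1
            if which == "b":
                ztVr = float(xj @ (b0 - (u0 * t0 + u1 * t1))) / sigma0_sq
            else:
                ztVr = float(xj @ (b1 - (u0 * t0 + u1 * t1))) / sigma0_sq
            ztVz = float(x_sq[:, j] @ gz) / sigma0_sq
            v = ztVz + 1.0 / slab_vars[j]
            mean = ztVr / v
            log_bf = -0.5 * np.log(slab_vars[j] * v) + 0.5 * mean * mean * v
            logit = np.clip(log_prior_odds + log_bf, -700, 700)
            include = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            r_flags[j] = 1 if include else 0
            if include:
                effects[j] = mean + rng.standard_normal() / np.sqrt(v)
                slab_vars[j] = _inv_gamma(
                    rng, priors.a + 0.5, priors.b + 0.5 * effects[j] ** 2
                )
                b0 -= xj * m_i * effects[j] if which == "b" else xj * st_i * effects[j]
                b1 -= xj * st_i * effects[j] if which == "b" else xj * stt_i * effects[j]
            else:
                effects[j] = 0.0
                slab_vars[j] = _inv_gamma(rng, priors.a, priors.b)

    for it in range(n_iter):
        # Woodbury blocks for V_i^{-1} = (I - W_i M_i^{-1} W_i^T / ...) / sigma0^2
        # with M_i = sigma0^2 Sigma^{-1} + W_i^T W_i
        Sig_inv = np.linalg.inv(Sigma)
        M00 = sigma0_sq * Sig_inv[0, 0] + m_i
        M01 = sigma0_sq * Sig_inv[0, 1] + st_i
        M11 = sigma0_sq * Sig_inv[1, 1] + stt_i
        det = M00 * M11 - M01 * M01
        Minv00 = M11 / det
        Minv01 = -M01 / det
        Minv11 = M00 / det
        g_int = m_i - (m_i * m_i * Minv00 + 2 * m_i * st_i * Minv01 + st_i * st_i * Minv11)
        g_slo = stt_i - (st_i * st_i * Minv00 + 2 * st_i * stt_i * Minv01 + stt_i * stt_i * Minv11)

        # per-individual W_i^T r_i of the marginal residual (no random effects)
        r_marg = y - W @ alpha - Zb @ beta - Zg @ gamma
        b0 = np.bincount(ind, weights=r_marg, minlength=n)
        b1 = np.bincount(ind, weights=r_marg * t, minlength=n)
        state = (b0, b1, Minv00, Minv01, Minv11, g_int, g_slo)

        # (i) spike-and-slab marker effects, intercept then slope
        spike_slab_sweep(r_b, beta, sv_b, "b", state)
        spike_slab_sweep(r_g, gamma, sv_g, "g", state)

        # (ii) fixed effects by collapsed GLS (flat prior)
        b0 += m_i * alpha[0] + st_i * alpha[1]
        b1 += st_i * alpha[0] + stt_i * alpha[1]
        t0 = Minv00 * b0 + Minv01 * b1
        t1 = Minv01 * b0 + Minv11 * b1
        rhs0 = float(np.sum(b0 - (m_i * t0 + st_i * t1))) / sigma0_sq
        rhs1 = float(np.sum(b1 - (st_i * t0 + stt_i * t1))) / sigma0_sq
        A00 = float(np.sum(g_int)) / sigma0_sq
        A11 = float(np.sum(g_slo)) / sigma0_sq
        A01 = float(
            np.sum(
                st_i
                - (m_i * st_i * Minv00 + (m_i * stt_i + st_i * st_i) * Minv01 + st_i * stt_i * Minv11)
            )
        ) / sigma0_sq
        A = np.array([[A00, A01], [A01, A11]])
        alpha = rng.multivariate_normal(np.linalg.solve(A, [rhs0, rhs1]), np.linalg.inv(A))

        # (iii) random effects from their exact bivariate conditional
        r_marg = y - W @ alpha - Zb @ beta - Zg @ gamma
        c0 = np.bincount(ind, weights=r_marg, minlength=n) / sigma0_sq
        c1 = np.bincount(ind, weights=r_marg * t, minlength=n) / sigma0_sq
        p00 = m_i / sigma0_sq + Sig_inv[0, 0]
        p01 = st_i / sigma0_sq + Sig_inv[0, 1]
        p11 = stt_i / sigma0_sq + Sig_inv[1, 1]
        pdet = p00 * p11 - p01 * p01
        mu0 = (p11 * c0 - p01 * c1) / pdet
        mu1 = (p00 * c1 - p01 * c0) / pdet
        l00 = np.sqrt(p00)
        l01 = p01 / l00
        l11 = np.sqrt(np.maximum(p11 - l01 * l01, 1e-300))
        z1 = rng.standard_normal(n)
        u1v = z1 / l11
        u0v = (rng.standard_normal(n) - l01 * u1v) / l00
        a_re[:, 0] = mu0 + u0v
        a_re[:, 1] = mu1 + u1v

        # (iv) Sigma | a ~ Inv-Wishart(Psi + sum a a^T, upsilon + n)
        scale = priors.Psi + a_re.T @ a_re
        for _ in range(5):
            Sigma = np.atleast_2d(
                invwishart.rvs(df=priors.upsilon + n, scale=scale, random_state=rng)
            )
            try:
                np.linalg.cholesky(Sigma)
                break
            except np.linalg.LinAlgError:
                pd_resamples += 1
                scale = scale + 1e-8 * np.eye(2)

        # (v) sigma0^2 under Jeffreys: scaled inverse-chi-square
        resid = r_marg - a_re[ind, 0] - a_re[ind, 1] * t
        sigma0_sq = max(float(resid @ resid) / rng.chisquare(n_obs), 1e-12)

        if it >= burn_in and (it - burn_in) % thin == 0:
            draws["alpha0"].append(alpha[0])
            draws["alpha1"].append(alpha[1])
            draws["Sigma"].append(Sigma.copy())
            draws["sigma0_sq"].append(sigma0_sq)
            draws["beta"].append(beta.copy())
            draws["gamma"].append(gamma.copy())
            draws["r_beta"].append(r_b.copy())
            draws["r_gamma"].append(r_g.copy())

    for k in draws:
        draws[k] = np.asarray(draws[k])

    pip_b, lfdr_b = compute_pip(draws["r_beta"])
    pip_g, lfdr_g = compute_pip(draws["r_gamma"])
    markers = pd.DataFrame(
        {
            "marker": genotypes.markers,
            "pip_intercept": pip_b,
            "lfdr_intercept": lfdr_b,
            "effect_intercept": draws["beta"].mean(axis=0),
            "pip_slope": pip_g,
            "lfdr_slope": lfdr_g,
            "effect_slope": draws["gamma"].mean(axis=0),
        }
    )
    summary = PosteriorSummary(
        markers=markers,
        alpha0=float(np.mean(draws["alpha0"])),
        alpha1=float(np.mean(draws["alpha1"])),
        Sigma=draws["Sigma"].mean(axis=0),
        sigma0_sq=float(np.mean(draws["sigma0_sq"])),
        diagnostics={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "n_retained": len(draws["alpha0"]),
            "pd_resamples": pd_resamples,
            "seed": seed,
        },
    )
    return draws, summary


def reduced_model_sampler(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    priors: BLMMPriors | None = None,
    n_iter: int = 20000,
    burn_in: int = 10000,
    seed: int = 0,
    thin: int = 1,
) -> PosteriorSummary:
    """Reduced model for traits with two or three assessments per tree:
    random intercepts only, no slope effects.

    y_ik = a0 + alpha_i0 + sum_j x_ij beta_j + eps_ik, with
    alpha_i0 ~ N(0, tau^2) and tau^2 ~ Inv-Gamma(upsilon/2, Psi_11/2)
    (the scalar analogue of the inverse-Wishart block).  The same
    collapsed indicator updates are used, with the scalar Woodbury
    identity replacing the 2x2 blocks.
    """
    priors = priors or BLMMPriors()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter (empty retained chain)")
    n_times = pd.unique(phenotypes["time"]).size
    if n_times > 3:
        raise ValueError(
            f"{n_times} time points: use the full model (gibbs_sampler) instead"
        )
    ind, _, y, x = _prepare_observations(phenotypes, genotypes)
    n, p = x.shape
    n_obs = y.size
    rng = np.random.default_rng(seed)
    w = priors.w
    log_prior_odds = np.log(w / (1.0 - w))

    Zb = x[ind] if p else np.zeros((n_obs, 0))
    m_i = np.bincount(ind, minlength=n).astype(float)
    x_sq = x * x

    ig_shape0 = priors.upsilon / 2.0
    ig_scale0 = priors.Psi[0, 0] / 2.0

    alpha0 = float(y.mean())
    a0 = np.zeros(n)
    tau_sq = 1.0
    beta = np.zeros(p)
    r_b = np.zeros(p, dtype=int)
    sv_b = np.ones(p)
    sigma0_sq = max(float(np.var(y)), 1e-6)

    draws = {"alpha0": [], "tau_sq": [], "sigma0_sq": [], "beta": [], "r_beta": []}
    for it in range(n_iter):
        M = sigma0_sq / tau_sq + m_i
        g = m_i - m_i * m_i / M

        r_marg = y - alpha0 - (Zb @ beta if p else 0.0)
        b0 = np.bincount(ind, weights=r_marg, minlength=n)

        for j in range(p):
            xj = x[:, j]
            if beta[j] != 0.0:
                b0 += xj * m_i * beta[j]
            ztVr = float(xj @ (b0 - m_i * b0 / M)) / sigma0_sq
            ztVz = float(x_sq[:, j] @ g) / sigma0_sq
            v = ztVz + 1.0 / sv_b[j]
            mean = ztVr / v
            log_bf = -0.5 * np.log(sv_b[j] * v) + 0.5 * mean * mean * v
            logit = np.clip(log_prior_odds + log_bf, -700, 700)
            include = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            r_b[j] = 1 if include else 0
            if include:
                beta[j] = mean + rng.standard_normal() / np.sqrt(v)
                sv_b[j] = _inv_gamma(rng, priors.a + 0.5, priors.b + 0.5 * beta[j] ** 2)
                b0 -= xj * m_i * beta[j]
            else:
                beta[j] = 0.0
                sv_b[j] = _inv_gamma(rng, priors.a, priors.b)

        # collapsed draw of the population mean (flat prior)
        b0 += m_i * alpha0
        A = float(np.sum(g)) / sigma0_sq
        rhs = float(np.sum(b0 - m_i * b0 / M)) / sigma0_sq
        alpha0 = rng.normal(rhs / A, 1.0 / np.sqrt(A))

        # random intercepts, then tau^2 and sigma0^2
        r_marg = y - alpha0 - (Zb @ beta if p else 0.0)
        c0 = np.bincount(ind, weights=r_marg, minlength=n) / sigma0_sq
        prec = m_i / sigma0_sq + 1.0 / tau_sq
        a0 = c0 / prec + rng.standard_normal(n) / np.sqrt(prec)
        tau_sq = _inv_gamma(rng, ig_shape0 + n / 2.0, ig_scale0 + 0.5 * float(a0 @ a0))
        resid = r_marg - a0[ind]
        sigma0_sq = max(float(resid @ resid) / rng.chisquare(n_obs), 1e-12)

        if it >= burn_in and (it - burn_in) % thin == 0:
            draws["alpha0"].append(alpha0)
            draws["tau_sq"].append(tau_sq)
            draws["sigma0_sq"].append(sigma0_sq)
            draws["beta"].append(beta.copy())
            draws["r_beta"].append(r_b.copy())

    for k in draws:
        draws[k] = np.asarray(draws[k])

    if p:
        pip_b, lfdr_b = compute_pip(draws["r_beta"])
        eff_b = draws["beta"].mean(axis=0)
    else:
        pip_b = lfdr_b = eff_b = np.zeros(0)
    markers = pd.DataFrame(
        {
            "marker": genotypes.markers,
            "pip_intercept": pip_b,
            "lfdr_intercept": lfdr_b,
            "effect_intercept": eff_b,
        }
    )
    tau_mean = float(draws["tau_sq"].mean())
    return PosteriorSummary(
        markers=markers,
        alpha0=float(draws["alpha0"].mean()),
        alpha1=float("nan"),
        Sigma=np.array([[tau_mean, 0.0], [0.0, 0.0]]),
        sigma0_sq=float(draws["sigma0_sq"].mean()),
        diagnostics={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "n_retained": len(draws["alpha0"]),
            "seed": seed,
            "alpha0_draws": draws["alpha0"],
        },
    )
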