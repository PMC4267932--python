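"""Post-selection decision rules for the penalised marker screen.

Four complementary ways to attach uncertainty to markers selected by the
lasso:

* ``single_p_test`` — one-by-one OLS re-estimation of the selected markers
  with a t-test, Bonferroni-adjusted by the *total* marker count;
* ``multi_split_test`` — repeated sample splitting (select on one half,
  test on the other) with quantile aggregation of the per-split
  Bonferroni-adjusted p-values;
* ``covariance_test`` — the significance of each marker *entering* the
  solution path, with an asymptotic Exp(1) null for the test statistic;
* ``stability_selection`` — the selection frequency of each marker over
  repeated half-sample lasso fits, with a threshold calibrated to bound
  the expected number of falsely selected markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lasso import LassoPath, cv_lasso_fit, lasso_path, refit_ols_single

__all__ = [
    "single_p_test",
    "multi_split_test",
    "covariance_test",
    "stability_selection",
    "ssp_threshold",
    "SSPConfig",
    "build_test_report",
]


def single_p_test(
    X: np.ndarray,
    y: np.ndarray,
    selected_markers,
    p_total: int,
) -> dict[int, float]:
    """Bonferroni-adjusted simple-regression re-tests of selected markers.

    Each selected marker is re-estimated alone (with intercept) by OLS and
    t-tested; the raw two-sided p-value is multiplied by the total marker
    count of the dataset and capped at 1.  Markers outside the selection
    are absent from the result.
    """
    if p_total < 1:
        raise ValueError("p_total must be positive")
    X = np.asarray(X, dtype=float)
    out: dict[int, float] = {}
    for j in selected_markers:
        _, _, _, p_raw = refit_ols_single(X[:, j], y)
        out[int(j)] = min(1.0, p_raw * p_total)
    return out


def _ols_multiple_pvalues(X_sel: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values of each coefficient in a multiple OLS fit
    (with intercept)."""
    from scipy import stats

    n, k = X_sel.shape
    Z = np.column_stack([np.ones(n), X_sel])
    dof = n - k - 1
    if dof <= 0:
        return np.ones(k)
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < k + 1:
        return np.ones(k)
    resid = y - Z @ coef
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov)[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef[1:] / se
    return 2.0 * stats.t.sf(np.abs(tstat), dof)


def _aggregate_split_pvalues(p_matrix: np.ndarray, gamma_min: float = 0.05) -> np.ndarray:
    """Quantile aggregation of per-split p-values.

    For each marker, Q(gamma) = min(1, empirical gamma-quantile of
    {p_b / gamma}); the aggregated p-value is
    min(1, (1 - log gamma_min) * inf over gamma in [gamma_min, 1] Q(gamma)).
    """
    gammas = np.linspace(gamma_min, 1.0, 96)
    # gamma-quantile of {p_b / gamma} equals quantile(p, gamma) / gamma
    quants = np.quantile(p_matrix, gammas, axis=0)  # (n_gammas, p)
    Q = np.minimum(1.0, quants / gammas[:, None])
    return np.minimum(1.0, (1.0 - np.log(gamma_min)) * Q.min(axis=0))


def multi_split_test(
    X: np.ndarray,
    y: np.ndarray,
    n_splits: int = 100,
    seed: int = 0,
    n_folds: int = 10,
) -> np.ndarray:
    """Multi-split test: select on one half, t-test on the other.

    Per split, a cross-validated lasso on the first half selects a marker
    subset; the second half provides multiple-regression t-tests of those
    markers, Bonferroni-adjusted by the selected-set size.  Markers not
    selected in a split receive p = 1 for that split.  The per-split
    p-values are combined by quantile aggregation and capped at 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 20:
        raise ValueError("multi-split test needs at least 20 individuals")
    rng = np.random.default_rng(seed)
    p_splits = np.ones((n_splits, p))
    half = n // 2
    for b in range(n_splits):
        perm = rng.permutation(n)
        first, second = perm[:half], perm[half:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cv_lasso_fit(
                X[first], y[first], n_folds=min(n_folds, half), seed=int(rng.integers(2**31))
            )
        sel = fit.selected
        if sel.size == 0:
            continue
        praw = _ols_multiple_pvalues(X[np.ix_(second, sel)], y[second])
        p_splits[b, sel] = np.minimum(1.0, praw * sel.size)
    return _aggregate_split_pvalues(p_splits)


def _restricted_coef(
    path: LassoPath, Xs: np.ndarray, yc: np.ndarray, A: list[int], lam: float
) -> np.ndarray:
    """Lasso refit restricted to the columns in A, evaluated at lam."""
    b = np.zeros(Xs.shape[1])
    if not A:
        return b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = lasso_path(Xs[:, A], yc, standardize=False, fit_intercept=False)
    lam_eff = max(lam, float(sub.lambdas[-1])) if not sub.complete else lam
    b[A] = sub.coef_std_at(lam_eff)
    return b


def covariance_test(
    path: LassoPath,
    X: np.ndarray,
    y: np.ndarray,
    sigma_sq="estimate",
    max_entries: int | None = None,
) -> pd.DataFrame:
    """Covariance test along the lasso path.

    At the k-th entry knot (penalty lambda_k, next knot lambda_{k+1}), the
    statistic is

        T_k = (<y, X b(lambda_{k+1})> - <y, X_A b~_A(lambda_{k+1})>) / sigma^2

    where A is the active set just before the entry and b~_A the lasso
    solution restricted to A.  Under the null that all signal variables
    are already in A, T_k is asymptotically Exp(1), giving p = exp(-T_k).

    ``sigma_sq="estimate"`` uses the full-model OLS residual variance when
    n > p + 1 and the cross-validated lasso residual variance otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    if sigma_sq == "estimate":
        if n > p + 1:
            Z = np.column_stack([np.ones(n), X])
            coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ coef
            sigma_sq = float(resid @ resid / (n - p - 1))
        else:
            sigma_sq = cv_lasso_fit(X, y).resid_var
    sigma_sq = float(sigma_sq)
    if sigma_sq <= 0:
        raise ValueError("residual variance must be positive")

    # reconstruct the path's internal design so inner products are consistent
    Xs = (X - path.x_mean) / path.x_scale
    if path.dropped_constant:
        Xs[:, path.dropped_constant] = 0.0
    yc = y - path.y_mean

    rows = []
    for k in range(1, len(path.lambdas)):
        prev_set = set(path.active_sets[k - 1])
        cur_set = set(path.active_sets[k])
        # an entry event happened at knot k-1's lambda if the set grew
        entered = cur_set - prev_set
        if not entered:
            continue
        lam_next = float(path.lambdas[k])
        b_full = path.coef_std_at(lam_next)
        b_restr = _restricted_coef(path, Xs, yc, sorted(prev_set), lam_next)
        T = (yc @ (Xs @ b_full) - yc @ (Xs @ b_restr)) / sigma_sq
        marker = sorted(entered)[0]
        rows.append({"marker": marker, "T": float(T), "p": float(np.exp(-max(T, 0.0)))})
        if max_entries is not None and len(rows) >= max_entries:
            break
    return pd.DataFrame(rows, columns=["marker", "T", "p"])


class SSPConfig:
    """Stability-selection configuration.

    ``q_target`` is the per-subsample active-set size (the q of the
    expected-false-positive bound); ``ev_bound`` the tolerated expected
    number of falsely selected markers.
    """

    def __init__(
        self,
        n_subsamples: int = 1000,
        subsample_fraction: float = 0.5,
        q_target: int = 10,
        ev_bound: float = 1.0,
    ):
        if n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if not 0 < subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if q_target < 1:
            raise ValueError("q_target must be >= 1")
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.q_target = q_target
        self.ev_bound = ev_bound


def stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SSPConfig | None = None,
    seed: int = 0,
    return_indices: bool = False,
):
    """Selection probability of each marker over half-sample lasso fits.

    Each subsample (drawn without replacement) contributes the active set
    at the path knot whose size is closest to ``cfg.q_target`` (earliest
    knot on ties); the SSP is the per-marker selection frequency.
    """
    cfg = cfg or SSPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if cfg.q_target > p:
        raise ValueError("q_target exceeds the marker count")
    m = int(round(n * cfg.subsample_fraction))
    if m < 10:
        raise ValueError("subsamples would have fewer than 10 individuals")
    rng = np.random.default_rng(seed)
    counts = np.zeros(p)
    index_log = []
    for _ in range(cfg.n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        index_log.append(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pp = lasso_path(X[idx], y[idx], max_knots=4 * cfg.q_target + 4)
        sizes = np.array([len(a) for a in pp.active_sets])
        k = int(np.argmin(np.abs(sizes - cfg.q_target)))
        for j in pp.active_sets[k]:
            counts[j] += 1
    ssp = counts / cfg.n_subsamples
    if return_indices:
        return ssp, index_log
    return ssp


def ssp_threshold(p_markers: int, q_avg: float, ev_bound: float) -> float:
    """Minimal SSP threshold bounding the expected false selections.

    From E(V) <= q^2 / ((2 pi - 1) p): pi = (1 + q^2/(E(V) p)) / 2,
    reported to two decimals.  Raises when the implied threshold leaves
    the meaningful range (0.5, 1].
    """
    if p_markers < 1 or q_avg <= 0 or ev_bound <= 0:
        raise ValueError("p_markers, q_avg and ev_bound must be positive")
    pi = 0.5 * (1.0 + q_avg**2 / (ev_bound * p_markers))
    if pi <= 0.5 or pi > 1.0:
        raise ValueError(f"infeasible threshold pi = {pi:.3f}")
    return round(pi, 2)


def build_test_report(
    X: np.ndarray,
    y: np.ndarray,
    marker_ids: list[str] | None = None,
    n_splits: int = 100,
    ssp_config: SSPConfig | None = None,
    seed: int = 0,
    cv_seed: int | None = None,
) -> pd.DataFrame:
    """Run the lasso screen plus all four decision rules on one latent trait.

    Returns one row per marker with columns ``marker``, ``lasso_effect``,
    ``ols_effect``, ``single_p`` (NaN for unselected markers), ``mst_p``,
    ``cov_p`` (NaN for markers that never enter the path), ``ssp``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31)) if cv_seed is None else cv_seed

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cv_lasso_fit(X, y, seed=cv_seed)
    selected = fit.selected
    singles = single_p_test(X, y, selected, p_total=p)
    mst = multi_split_test(X, y, n_splits=n_splits, seed=int(rng.integers(2**31)))
    cov = covariance_test(fit.path, X, y)
    cov_p = {int(r.marker): float(r.p) for r in cov.itertuples()}
    ssp = stability_selection(X, y, ssp_config, seed=int(rng.integers(2**31)))

    ols_effect = np.full(p, np.nan)
    for j in selected:
        ols_effect[j] = refit_ols_single(X[:, j], y)[0]

    ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(p)]
    return pd.DataFrame(
        {
            "marker": ids,
            "lasso_effect": fit.coefficients,
            "ols_effect": ols_effect,
            "single_p": [singles.get(j, np.nan) for j in range(p)],
            "mst_p": mst,
            "cov_p": [cov_p.get(j, np.nan) for j in range(p)],
            "ssp": ssp,
        }
    )
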