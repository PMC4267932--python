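"""L1-penalised multi-marker regression via the LARS-lasso homotopy.

The path solves, for every penalty level lambda simultaneously,

    min_b  1/2 * ||y - X b||^2 + lambda * ||b||_1

tracking the exact knots at which markers enter or leave the active set.
Between knots the coefficients are piecewise-linear in lambda, so the
solution at any penalty follows by interpolation.  The homotopy form is
needed downstream: the covariance test is constructed from successive
knots, and stability selection reads the active set of a target size off
each subsample's path.

Predictors are by default standardised internally (zero mean, unit
standard deviation) and effects mapped back to the original 0/1 marker
coding; the intercept is never penalised.  The penalty is tuned by
10-fold cross-validation at the CV-error minimum, with seeded fold
assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LassoPath", "LassoFit", "lasso_path", "cv_lasso_fit", "refit_ols_single"]

_TINY = 1e-12


@dataclass
class LassoPath:
    """Exact homotopy path: knots, active sets and coefficients.

    ``coefs`` holds the solution at each knot on the (internal)
    standardised scale; :meth:`coef_at` interpolates and returns original
    scale effects plus intercept.  ``lambdas`` is strictly decreasing and
    ends at 0 when the path ran to completion.
    """

    lambdas: np.ndarray
    coefs: np.ndarray  # n_knots x p, standardised scale
    active_sets: list[list[int]]
    entry_order: list[int]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    complete: bool
    dropped_constant: list[int] = field(default_factory=list)

    @property
    def lambda_max(self) -> float:
        return float(self.lambdas[0])

    def coef_std_at(self, lmbda: float) -> np.ndarray:
        """Standardised-scale coefficients at an arbitrary penalty."""
        if lmbda >= self.lambdas[0]:
            return np.zeros(self.coefs.shape[1])
        if lmbda < self.lambdas[-1] - _TINY:
            raise ValueError(
                f"lambda {lmbda} below the last computed knot {self.lambdas[-1]}; "
                "the path was truncated"
            )
        lmbda = max(lmbda, float(self.lambdas[-1]))
        k = int(np.searchsorted(-self.lambdas, -lmbda, side="left"))
        if k == 0:
            return self.coefs[0].copy()
        lo, hi = self.lambdas[k], self.lambdas[k - 1]
        w = 0.0 if hi == lo else (hi - lmbda) / (hi - lo)
        return self.coefs[k - 1] + w * (self.coefs[k] - self.coefs[k - 1])

    def coef_at(self, lmbda: float) -> tuple[float, np.ndarray]:
        """(intercept, coefficients) on the original predictor scale."""
        b = self.coef_std_at(lmbda) / self.x_scale
        intercept = self.y_mean - float(b @ self.x_mean)
        return intercept, b

    def predict(self, X: np.ndarray, lmbda: float) -> np.ndarray:
        a, b = self.coef_at(lmbda)
        return a + X @ b


@dataclass
class LassoFit:
    """Cross-validated lasso solution for one latent trait."""

    lambda_star: float
    intercept: float
    coefficients: np.ndarray
    cv_curve: np.ndarray  # columns: lambda, mean CV error, se
    resid_var: float
    path: LassoPath
    fold_assignment: np.ndarray

    @property
    def selected(self) -> np.ndarray:
        return np.nonzero(self.coefficients != 0)[0]


def _prepare(X, y, standardize, fit_intercept):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a vector matching X's rows")
    if n < 2:
        raise ValueError("at least two observations required")
    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
    else:
        x_mean = np.zeros(p)
        y_mean = 0.0
    Xc = X - x_mean
    if standardize:
        x_scale = Xc.std(axis=0)
    else:
        x_scale = np.ones(p)
    dropped = np.nonzero(x_scale <= _TINY)[0]
    if dropped.size:
        warnings.warn(
            f"excluding {dropped.size} constant marker column(s) from the penalised fit",
            stacklevel=3,
        )
        x_scale = np.where(x_scale <= _TINY, 1.0, x_scale)
    Xs = Xc / x_scale
    Xs[:, dropped] = 0.0
    return Xs, y - y_mean, x_mean, x_scale, y_mean, list(dropped)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    standardize: bool = True,
    fit_intercept: bool = True,
    max_knots: int | None = None,
) -> LassoPath:
    """Compute the exact LARS-lasso homotopy, including drop events.

    Constant (zero-variance) columns are excluded with a warning and keep
    zero coefficients throughout.  ``max_knots`` truncates the path after
    that many knots (used when only the first entries are needed).
    """
    Xs, yc, x_mean, x_scale, y_mean, dropped = _prepare(X, y, standardize, fit_intercept)
    n, p = Xs.shape

    c = Xs.T @ yc  # current correlations (at current lambda)
    usable = np.ones(p, dtype=bool)
    usable[dropped] = False

    lambdas = [float(np.max(np.abs(c[usable]))) if usable.any() else 0.0]
    coefs = [np.zeros(p)]
    active: list[int] = []
    signs: dict[int, float] = {}
    entry_order: list[int] = []
    active_sets: list[list[int]] = [[]]

    if lambdas[0] <= _TINY or not usable.any():
        return LassoPath(
            np.asarray([lambdas[0], 0.0]) if lambdas[0] > 0 else np.asarray([0.0]),
            np.vstack([coefs[0], coefs[0]]) if lambdas[0] > 0 else np.asarray(coefs),
            [[], []] if lambdas[0] > 0 else [[]],
            [],
            x_mean,
            x_scale,
            y_mean,
            True,
            dropped,
        )

    lam = lambdas[0]
    b = np.zeros(p)
    # first entry: marker with maximal |correlation| (lowest index on ties)
    j0 = int(np.argmax(np.where(usable, np.abs(c), -np.inf)))
    active.append(j0)
    signs[j0] = np.sign(c[j0])
    entry_order.append(j0)

    max_events = 20 * p + 100  # guard against numerically cycling events
    while True:
        if len(lambdas) > max_events:
            complete = False
            break
        A = np.asarray(active, dtype=int)
        s_A = np.asarray([signs[j] for j in active])
        G = Xs[:, A].T @ Xs[:, A]
        try:
            d_A = np.linalg.solve(G, s_A)
        except np.linalg.LinAlgError:
            d_A = np.linalg.lstsq(G, s_A, rcond=None)[0]
        a = Xs.T @ (Xs[:, A] @ d_A)  # rate of correlation change per unit lambda

        # candidate join events for inactive usable markers
        best_join_lam = -np.inf
        best_join_j = -1
        for j in np.nonzero(usable)[0]:
            if j in signs:
                continue
            for sgn in (1.0, -1.0):
                denom = sgn - a[j]
                if abs(denom) < _TINY:
                    continue
                cand = (c[j] - lam * a[j]) / denom
                if _TINY < cand < lam - 1e-10 and cand > best_join_lam:
                    best_join_lam, best_join_j = cand, int(j)
                elif cand > _TINY and abs(cand - best_join_lam) <= 1e-10 and int(j) < best_join_j:
                    best_join_j = int(j)

        # candidate drop events for active markers
        best_drop_lam = -np.inf
        best_drop_j = -1
        for idx, j in enumerate(active):
            if abs(d_A[idx]) < _TINY:
                continue
            cand = lam + b[j] / d_A[idx]
            if _TINY < cand < lam - 1e-10 and cand > best_drop_lam:
                best_drop_lam, best_drop_j = cand, int(j)

        next_lam = max(best_join_lam, best_drop_lam, 0.0)
        # advance coefficients to next_lam
        b = b.copy()
        b[A] = b[A] + (lam - next_lam) * d_A
        c = c - (lam - next_lam) * a

        if best_drop_lam >= best_join_lam and best_drop_j >= 0 and best_drop_lam > 0.0:
            b[best_drop_j] = 0.0
            active.remove(best_drop_j)
            del signs[best_drop_j]
            event = "drop"
        elif best_join_j >= 0 and best_join_lam > 0.0:
            active.append(best_join_j)
            signs[best_join_j] = np.sign(c[best_join_j])
            if best_join_j not in entry_order:
                entry_order.append(best_join_j)
            event = "join"
        else:
            event = "end"

        lam = next_lam
        lambdas.append(lam)
        coefs.append(b.copy())
        active_sets.append(sorted(active))

        if event == "end" or lam <= _TINY:
            complete = True
            break
        if max_knots is not None and len(lambdas) >= max_knots:
            complete = False
            break

    return LassoPath(
        np.asarray(lambdas),
        np.asarray(coefs),
        active_sets,
        entry_order,
        x_mean,
        x_scale,
        y_mean,
        complete,
        dropped,
    )


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels by seeded permutation into contiguous blocks."""
    perm = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        assign[chunk] = f
    return assign


def cv_lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> LassoFit:
    """Lasso with the penalty chosen by cross-validation at the CV minimum.

    The CV grid is the full-data path's knot sequence; per fold, the path
    is recomputed on the training block and held-out squared errors are
    pooled.  Coefficients are refitted on the full data at the selected
    penalty.  Residual variance is RSS / (n - k - 1) with k the number of
    selected markers (RSS / n when the degrees of freedom run out).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"n = {n} below n_folds = {n_folds}; use fewer folds")

    full = lasso_path(X, y, standardize=standardize)
    grid = full.lambdas
    assign = make_folds(n, n_folds, seed)

    sq_err = np.zeros((n_folds, grid.size))
    counts = np.zeros(n_folds)
    for f in range(n_folds):
        test = assign == f
        train = ~test
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pf = lasso_path(X[train], y[train], standardize=standardize)
        counts[f] = test.sum()
        for gi, lam in enumerate(grid):
            lam_eff = max(lam, float(pf.lambdas[-1])) if not pf.complete else lam
            pred = pf.predict(X[test], lam_eff)
            sq_err[f, gi] = np.mean((y[test] - pred) ** 2)

    mean_cv = np.average(sq_err, axis=0, weights=counts)
    se_cv = np.std(sq_err, axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean_cv))  # ties: argmin takes the largest lambda (earliest)
    lambda_star = float(grid[best])

    intercept, coef = full.coef_at(lambda_star)
    resid = y - intercept - X @ coef
    k = int(np.count_nonzero(coef))
    dof = n - k - 1
    resid_var = float(resid @ resid / dof) if dof > 0 else float(resid @ resid / n)

    cv_curve = np.column_stack([grid, mean_cv, se_cv])
    return LassoFit(lambda_star, intercept, coef, cv_curve, resid_var, full, assign)


def refit_ols_single(x_j: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Simple (single marker + intercept) OLS re-estimate with a t-test.

    Returns (effect, standard error, t statistic, two-sided p on n-2 df).
    """
    x_j = np.asarray(x_j, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x_j) <= _TINY:
        raise ValueError("constant marker column cannot be re-tested")
    res = stats.linregress(x_j, y)
    n = x_j.size
    if res.stderr > 0:
        tstat = res.slope / res.stderr
    else:
        tstat = np.inf * np.sign(res.slope) if res.slope != 0 else 0.0
    return float(res.slope), float(res.stderr), float(tstat), float(res.pvalue)
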