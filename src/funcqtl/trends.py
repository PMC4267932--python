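"""Per-individual linear trend fits producing latent intercept/slope traits.

Step 1 of the multilevel analysis: each individual's repeated measurements
y_ik are fitted by ordinary least squares to y = mu0 + mu1 * t with centred
time codes, so that with complete data the intercept estimate equals the
individual's mean across rings.  The fitted (mu0_hat, mu1_hat) pairs are
treated as new latent traits downstream.  Individuals with more than five
of the nine measurements missing (fewer than four observations) are
excluded and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndividualTrend", "fit_individual_trend", "build_latent_traits"]


@dataclass
class IndividualTrend:
    individual_id: str
    mu0_hat: float
    mu1_hat: float
    n_obs: int
    resid_var_hat: float | None  # None when n_obs == 2 (0 residual df)


def fit_individual_trend(times, values, individual_id: str = "") -> IndividualTrend:
    """Exact OLS fit of one individual's linear trend.

    Residual variance uses denominator (n_obs - 2) and is flagged ``None``
    when only two observations are available.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must align")
    n = t.size
    if n < 2:
        raise ValueError("at least two observations are required for a slope")
    if np.unique(t).size < 2:
        raise ValueError("times must not all coincide")
    tbar, ybar = t.mean(), y.mean()
    stt = np.sum((t - tbar) ** 2)
    mu1 = np.sum((t - tbar) * (y - ybar)) / stt
    mu0 = ybar - mu1 * tbar
    resid = y - mu0 - mu1 * t
    rv = float(np.sum(resid**2) / (n - 2)) if n > 2 else None
    return IndividualTrend(individual_id, float(mu0), float(mu1), n, rv)


def build_latent_traits(
    phenotypes: pd.DataFrame,
    min_obs: int = 4,
    trait_id: str | None = None,
) -> pd.DataFrame:
    """Fit trends for every individual of one trait's long-format table.

    Returns one row per individual with columns ``individual_id``,
    ``mu0_hat``, ``mu1_hat``, ``n_obs``, ``resid_var_hat``, ``retained``,
    ``reason``.  Individuals with fewer than ``min_obs`` observations (the
    more-than-five-missing-of-nine rule) are excluded with a reason.
    """
    df = phenotypes
    if trait_id is not None:
        df = df[df["trait_id"] == trait_id]
    if df.empty:
        raise ValueError("empty phenotype table")
    rows = []
    for ind, grp in df.groupby("individual_id", sort=True):
        n = len(grp)
        if n < min_obs:
            rows.append(
                {
                    "individual_id": ind,
                    "mu0_hat": np.nan,
                    "mu1_hat": np.nan,
                    "n_obs": n,
                    "resid_var_hat": np.nan,
                    "retained": False,
                    "reason": f"only {n} observations (< {min_obs})",
                }
            )
            continue
        fit = fit_individual_trend(grp["time"].to_numpy(), grp["value"].to_numpy(), ind)
        rows.append(
            {
                "individual_id": ind,
                "mu0_hat": fit.mu0_hat,
                "mu1_hat": fit.mu1_hat,
                "n_obs": n,
                "resid_var_hat": np.nan if fit.resid_var_hat is None else fit.resid_var_hat,
                "retained": True,
                "reason": "",
            }
        )
    return pd.DataFrame(rows)
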