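"""QTL classification, explained variance and genotype trajectories.

A marker is *suggestive* when any of the Bonferroni single-marker p, the
multi-split p, the covariance-test p or its marker-level BFDR (the LFDR)
falls below 0.2, or its stability-selection probability reaches the
dataset's suggestive threshold.  It is *significant* when at least two of
the three p-value statistics are at or below 0.05, or the SSP reaches the
stricter threshold, or the marker belongs to the BFDR-selected set at
alpha = 0.05.  The SSP thresholds are calibrated per dataset from the
expected-false-positive bound (see ``inference.ssp_threshold``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blmm import bfdr_select
from .rings import inverse_transform_proportion, transform_proportion

__all__ = [
    "DatasetProfile",
    "QTLCall",
    "TrajectoryPrediction",
    "classify_qtl",
    "h2_qtl",
    "predict_genotype_trajectories",
    "effect_size_ratios",
]

_DEG = 180.0 / np.pi


@dataclass
class DatasetProfile:
    """Dataset-level constants needed by the decision rules."""

    p_markers: int
    ssp_suggestive: float  # threshold bounding E(false positives) < 2
    ssp_significant: float  # threshold bounding E(false positives) < 1


@dataclass
class QTLCall:
    marker: str
    trait_id: str
    target: str  # intercept | slope | time-point
    level: str  # none | suggestive | significant
    rules_fired: list[str]
    lasso_effect: float
    blmm_effect: float


@dataclass
class TrajectoryPrediction:
    """Predicted proportion-trait trajectories for the two marker classes
    of a 1:1-segregating QTL, on original (%) and transformed (degree)
    scales."""

    ages: np.ndarray
    population_pct: np.ndarray
    present_pct: np.ndarray
    absent_pct: np.ndarray
    population_deg: np.ndarray
    present_deg: np.ndarray
    absent_deg: np.ndarray


def classify_qtl(
    report: pd.DataFrame,
    bayes: pd.DataFrame | None,
    profile: DatasetProfile,
    trait_id: str = "trait",
    target: str = "intercept",
    alpha_bfdr: float = 0.05,
) -> list[QTLCall]:
    """Combine the four lasso statistics and the Bayesian posterior into
    per-marker suggestive/significant calls.

    ``report`` needs columns marker, single_p, mst_p, cov_p, ssp,
    lasso_effect; ``bayes`` (optional) columns marker and
    lfdr_<target>/effect_<target>.  A pure function of the recorded
    statistics: calls are replayable from the saved tables alone.
    """
    if profile is None:
        raise ValueError("a dataset profile is required")
    lfdr_col = f"lfdr_{target}" if target in ("intercept", "slope") else "lfdr_intercept"
    eff_col = f"effect_{target}" if target in ("intercept", "slope") else "effect_intercept"
    lfdr = {}
    blmm_eff = {}
    bfdr_set: set[str] = set()
    if bayes is not None and lfdr_col in bayes.columns:
        lfdr = dict(zip(bayes["marker"], bayes[lfdr_col]))
        blmm_eff = dict(zip(bayes["marker"], bayes[eff_col]))
        sel_idx, _ = bfdr_select(bayes[lfdr_col].to_numpy(), alpha=alpha_bfdr)
        bfdr_set = set(bayes["marker"].iloc[sel_idx])

    calls = []
    for row in report.itertuples():
        stats = {
            "single_p": getattr(row, "single_p", np.nan),
            "mst_p": getattr(row, "mst_p", np.nan),
            "cov_p": getattr(row, "cov_p", np.nan),
        }
        marker_lfdr = lfdr.get(row.marker, np.nan)
        ssp = getattr(row, "ssp", np.nan)

        fired: list[str] = []
        suggestive = False
        for name, v in {**stats, "bfdr": marker_lfdr}.items():
            if np.isfinite(v) and v < 0.2:
                suggestive = True
                fired.append(f"{name}<0.2")
        if np.isfinite(ssp) and ssp >= profile.ssp_suggestive:
            suggestive = True
            fired.append(f"ssp>={profile.ssp_suggestive}")

        n_small = sum(1 for v in stats.values() if np.isfinite(v) and v <= 0.05)
        significant = False
        if n_small >= 2:
            significant = True
            fired.append("two_p<=0.05")
        if np.isfinite(ssp) and ssp >= profile.ssp_significant:
            significant = True
            fired.append(f"ssp>={profile.ssp_significant}")
        if row.marker in bfdr_set:
            significant = True
            fired.append(f"bfdr_selected@{alpha_bfdr}")

        level = "significant" if significant else ("suggestive" if suggestive else "none")
        calls.append(
            QTLCall(
                marker=str(row.marker),
                trait_id=trait_id,
                target=target,
                level=level,
                rules_fired=fired,
                lasso_effect=float(getattr(row, "lasso_effect", np.nan)),
                blmm_effect=float(blmm_eff.get(row.marker, np.nan)),
            )
        )
    return calls


def h2_qtl(
    effects: dict[int, float],
    genotype_codes: np.ndarray,
    latent_values: np.ndarray | None = None,
    method: str = "mlasso",
    random_effect_var: float | None = None,
) -> float:
    """Fraction of latent-trait phenotypic variance explained by the
    selected QTL jointly.

    mLASSO route: Var_i(sum_j x_ij effect_j) / Var_i(latent trait).
    BLMM route: the denominator is the random-effect variance plus the
    genetic-score variance (the model's approximation to the latent-trait
    variance).
    """
    if not effects:
        return 0.0
    X = np.asarray(genotype_codes, dtype=float)
    cols = sorted(effects)
    score = X[:, cols] @ np.asarray([effects[j] for j in cols])
    num = float(np.var(score))
    if method == "mlasso":
        if latent_values is None:
            raise ValueError("mlasso H2 needs the latent trait values")
        denom = float(np.var(np.asarray(latent_values, dtype=float)))
    elif method == "blmm":
        if random_effect_var is None:
            raise ValueError("blmm H2 needs the random-effect variance")
        denom = float(random_effect_var) + num
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom <= 0:
        raise ValueError("zero latent-trait variance")
    h2 = num / denom
    if h2 > 1:
        warnings.warn("H2 above 1: effects and latent variance come from different fits")
    return h2


def predict_genotype_trajectories(
    pop_mean_pct: float,
    pop_trend_pct_per_yr: float,
    qtl_slope_effect_deg_per_yr: float,
    start_age: float,
    horizon_yr: float,
    n_steps: int | None = None,
) -> TrajectoryPrediction:
    """Predicted proportion-trait trajectories for the two genotype classes
    of a slope QTL.

    The population mean (percent) is moved to the arcsine-square-root
    (degree) scale; the population trend is linearised onto that scale via
    the delta method, dT/dp = 1/(2 sqrt(p (1-p))) at the mean.  With 0/1
    coding and 1:1 segregation the two genotype classes sit at +/- half
    the slope effect around the population slope.  Trajectories are linear
    on the transformed scale and back-transformed to percent (clipped with
    a warning if a prediction leaves [0, 100]).
    """
    if not 0 < pop_mean_pct < 100:
        raise ValueError("population mean must lie strictly inside (0, 100)%")
    steps = int(horizon_yr) if n_steps is None else n_steps
    ages = start_age + np.linspace(0.0, horizon_yr, steps + 1)
    p0 = pop_mean_pct / 100.0
    T0 = transform_proportion(p0)
    dT_dp = _DEG / (2.0 * np.sqrt(p0 * (1.0 - p0)))  # degrees per unit proportion
    pop_slope_deg = (pop_trend_pct_per_yr / 100.0) * dT_dp
    half = qtl_slope_effect_deg_per_yr / 2.0

    yrs = ages - start_age
    pop_deg = T0 + pop_slope_deg * yrs
    pres_deg = T0 + (pop_slope_deg + half) * yrs
    abs_deg = T0 + (pop_slope_deg - half) * yrs

    def back(deg):
        clipped = np.clip(deg, 0.0, 90.0)
        if np.any(clipped != deg):
            warnings.warn("back-transform left [0, 100]%: predictions clipped")
        return 100.0 * inverse_transform_proportion(clipped)

    return TrajectoryPrediction(
        ages=ages,
        population_pct=back(pop_deg),
        present_pct=back(pres_deg),
        absent_pct=back(abs_deg),
        population_deg=pop_deg,
        present_deg=pres_deg,
        absent_deg=abs_deg,
    )


def effect_size_ratios(
    effects: dict[str, float],
    references: dict[str, float],
) -> dict[str, float]:
    """Percent ratio of each QTL effect to its reference quantity.

    The reference is the population mean for intercept QTL and the
    transformed-scale population mean slope for slope QTL of proportion
    traits.  Returns 100 * |effect| / |reference| per QTL id.
    """
    out = {}
    for key, eff in effects.items():
        ref = references[key]
        if ref == 0:
            raise ValueError(f"zero reference for {key}")
        out[key] = 100.0 * abs(eff) / abs(ref)
    return out
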