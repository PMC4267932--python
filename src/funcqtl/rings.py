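"""Annual-ring segmentation and trait transforms.

Each position inside a ring is designated earlywood, transitionwood or
latewood from that ring's own density span: positions at or below
``WDmin + 0.2 (WDmax - WDmin)`` are earlywood, positions at or above
``WDmin + 0.8 (WDmax - WDmin)`` are latewood, the rest is transitionwood.
Ring summaries report the ring width (RW), the earlywood/latewood width
percentages (EP, LP) and the mean densities of the whole ring and its
components (WD, EWD, LWD).  Proportion traits are analysed on the
arcsine-square-root scale in degrees; consecutive calendar years are
recoded to symmetric integer codes centred on the middle year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import RadialProfile

__all__ = [
    "DegenerateRingError",
    "RingComponentSummary",
    "designate_components",
    "summarize_ring",
    "summarize_profile",
    "transform_proportion",
    "inverse_transform_proportion",
    "recode_time",
]

EARLYWOOD = "earlywood"
TRANSITION = "transitionwood"
LATEWOOD = "latewood"


class DegenerateRingError(ValueError):
    """Raised for rings whose density span is zero (WDmax == WDmin)."""


@dataclass
class RingComponentSummary:
    """Per-ring trait summary; component densities are ``None`` when the
    component has no positions (reported as absent, not zero)."""

    ring_id: int
    rw: float
    ep: float
    lp: float
    wd: float
    ewd: float | None
    lwd: float | None


def designate_components(ring_densities: np.ndarray) -> np.ndarray:
    """Label every position of one ring as earlywood/transition/latewood.

    Thresholds at 20% and 80% of the ring's own min-max density span;
    equality at a threshold is included in the respective component, and
    the earlywood test is applied first.
    """
    d = np.asarray(ring_densities, dtype=float)
    if d.size < 2:
        raise ValueError("a ring needs at least two positions")
    lo, hi = d.min(), d.max()
    if hi <= lo:
        raise DegenerateRingError("constant-density ring: WDmax == WDmin")
    span = hi - lo
    labels = np.full(d.shape, TRANSITION, dtype=object)
    labels[d <= lo + 0.2 * span] = EARLYWOOD
    labels[(d >= lo + 0.8 * span) & (labels == TRANSITION)] = LATEWOOD
    return labels


def _cell_widths(positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Width of the interval each sampled position represents, partitioning
    [lo, hi] at midpoints between neighbours."""
    edges = np.empty(positions.size + 1)
    edges[0] = lo
    edges[-1] = hi
    edges[1:-1] = 0.5 * (positions[1:] + positions[:-1])
    return np.diff(edges)


def summarize_ring(
    positions: np.ndarray,
    densities: np.ndarray,
    labels: np.ndarray,
    ring_id: int = 0,
    bounds: tuple[float, float] | None = None,
) -> RingComponentSummary:
    """Summarise one ring from positions, densities and component labels.

    EP/LP are the percentages of ring width covered by earlywood/latewood
    positions (each position weighted by the interval it represents); the
    component densities are unweighted means over the labelled positions.
    """
    pos = np.asarray(positions, dtype=float)
    den = np.asarray(densities, dtype=float)
    lab = np.asarray(labels)
    if not (pos.size == den.size == lab.size):
        raise ValueError("positions, densities and labels must align")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    lo, hi = bounds if bounds is not None else (pos[0], pos[-1])
    rw = hi - lo
    if rw <= 0:
        raise ValueError("ring width must be positive")
    w = _cell_widths(pos, lo, hi)
    ew = lab == EARLYWOOD
    lw = lab == LATEWOOD
    ep = 100.0 * w[ew].sum() / rw
    lp = 100.0 * w[lw].sum() / rw
    return RingComponentSummary(
        ring_id=ring_id,
        rw=rw,
        ep=ep,
        lp=lp,
        wd=den.mean(),
        ewd=den[ew].mean() if ew.any() else None,
        lwd=den[lw].mean() if lw.any() else None,
    )


def summarize_profile(profile: RadialProfile) -> pd.DataFrame:
    """Apply component designation and ring summarisation to every ring of
    a profile; returns one tidy row per ring."""
    rows = []
    for k, year in enumerate(profile.calendar_years):
        sl = profile.ring_slice(k)
        pos = profile.positions[sl]
        den = profile.density[sl]
        labels = designate_components(den)
        lo, hi = profile.ring_boundaries[k], profile.ring_boundaries[k + 1]
        s = summarize_ring(pos, den, labels, ring_id=k, bounds=(lo, hi))
        rows.append(
            {
                "ring_id": k,
                "year": int(year),
                "RW": s.rw,
                "EP": s.ep,
                "LP": s.lp,
                "WD": s.wd,
                "EWD": s.ewd,
                "LWD": s.lwd,
            }
        )
    return pd.DataFrame(rows)


_DEG = 180.0 / np.pi


def transform_proportion(p):
    """Arcsine-square-root transform of a proportion, in degrees."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p)) * _DEG
    return float(out) if out.ndim == 0 else out


def inverse_transform_proportion(deg):
    """Inverse of :func:`transform_proportion`: sin^2 of an angle in degrees."""
    deg = np.asarray(deg, dtype=float)
    if np.any((deg < 0) | (deg > 90)):
        raise ValueError("transformed values must lie in [0, 90] degrees")
    out = np.sin(deg / _DEG) ** 2
    return float(out) if out.ndim == 0 else out


def recode_time(calendar_years) -> np.ndarray:
    """Centre consecutive calendar years on the middle year.

    Nine years 1995..2003 become -4..4; an even count yields half-integer
    codes (e.g. 2006..2007 -> [-0.5, 0.5])."""
    years = np.asarray(calendar_years, dtype=float)
    if years.size == 0:
        raise ValueError("no years given")
    if years.size > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("calendar years must be consecutive")
    return years - years.mean()
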