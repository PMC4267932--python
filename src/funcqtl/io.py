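"""Plain-text readers/writers for the pipeline's tables.

All artefacts are delimited text: genotypes as a CSV with a header row of
marker ids and one row per individual, marker maps as 3-column TSV,
phenotypes as 4-column long CSV, latent traits / test reports / posterior
summaries as tidy CSV/TSV, and a JSON run manifest recording seeds and
parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenotypeMatrix, TruthRecord

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_marker_map",
    "read_marker_map",
    "write_phenotypes",
    "read_phenotypes",
    "write_truth",
    "write_profile",
    "read_profile",
    "write_manifest",
]


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    gm.to_frame().to_csv(path, index_label="individual_id")


def read_genotypes(path, marker_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="individual_id")
    if marker_map is None:
        marker_map = pd.DataFrame(
            {
                "marker_id": df.columns,
                "linkage_group": "u",
                "position_cm": np.nan,
            }
        )
    return GenotypeMatrix(list(df.index.astype(str)), marker_map, df.to_numpy(float))


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: TruthRecord, path) -> None:
    """Structured key-value record of the generating parameters plus the
    realised random effects (JSON)."""
    p = truth.params
    payload = {
        "alpha0": p.alpha0,
        "alpha1": p.alpha1,
        "Sigma": np.asarray(p.Sigma).tolist(),
        "sigma0_sq": p.sigma0_sq,
        "beta": np.asarray(p.beta).tolist(),
        "gamma": np.asarray(p.gamma).tolist(),
        "time_grid": np.asarray(p.time_grid).tolist(),
        "missing_rate": p.missing_rate,
        "seed": p.seed,
        "random_effects": truth.random_effects.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_profile(profile, positions_path, boundaries_path) -> None:
    pd.DataFrame(
        {"position_mm": profile.positions, "density": profile.density}
    ).to_csv(positions_path, index=False)
    pd.DataFrame(
        {
            "ring_id": np.arange(len(profile.calendar_years)),
            "start_mm": profile.ring_boundaries[:-1],
            "end_mm": profile.ring_boundaries[1:],
            "year": profile.calendar_years,
        }
    ).to_csv(boundaries_path, index=False)


def read_profile(positions_path, boundaries_path):
    from .synthetic import RadialProfile

    pts = pd.read_csv(positions_path)
    b = pd.read_csv(boundaries_path)
    boundaries = np.concatenate([b["start_mm"].to_numpy(float), [float(b["end_mm"].iloc[-1])]])
    return RadialProfile(
        positions=pts["position_mm"].to_numpy(float),
        density=pts["density"].to_numpy(float),
        ring_boundaries=boundaries,
        calendar_years=b["year"].to_numpy(int),
    )


def write_manifest(path, **entries) -> None:
    """JSON run manifest of seeds and parameters actually used."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=1, default=default))
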