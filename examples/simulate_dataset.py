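"""Simulate a full-sib mapping dataset and write it as delimited tables.

Generates 300 trees genotyped for 80 linked + 20 unmapped 1:1-segregating
markers and an earlywood-percentage-like trait (arcsine-square-root degree
scale) observed over nine annual rings, with two planted QTL: one shifting
the tree-level mean, one tilting the annual trend.
"""

from pathlib import Path

import numpy as np

from funcqtl import io, synthetic

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

genotypes, marker_map = synthetic.simulate_pedigree_genotypes(
    n_individuals=300,
    lg_layout=[(40, 12.0), (40, 12.0)],  # two linkage groups, ~12 cM spacing
    unmapped_count=20,
    seed=2024,
)

beta = np.zeros(100)
gamma = np.zeros(100)
beta[17] = 2.5    # intercept QTL: +2.5 deg on the transformed scale
gamma[91] = 0.23  # slope QTL: the size reported for the EP trend marker

params = synthetic.ep_default_params(100, beta=beta, gamma=gamma, seed=91)
phenotypes, truth = synthetic.simulate_longitudinal_traits(genotypes, params, trait_id="EP")

io.write_genotypes(genotypes, out / "genotypes.csv")
io.write_marker_map(marker_map, out / "marker_map.tsv")
io.write_phenotypes(phenotypes, out / "phenotypes.csv")
io.write_truth(truth, out / "truth.json")
io.write_manifest(
    out / "manifest.json",
    seed_genotypes=2024,
    seed_traits=91,
    n_individuals=300,
    n_markers=100,
    missing_rate=params.missing_rate,
)

n_cells = 300 * 9
print(f"wrote {out}/: genotypes 300 x 100, phenotype rows {len(phenotypes)}")
print(
    f"observed fraction {len(phenotypes) / n_cells:.3f} "
    f"(missing-at-random rate {params.missing_rate})"
)
freq = genotypes.codes.mean()
print(f"overall frequency of marker code 1: {freq:.3f} (1:1 segregation -> 0.5)")
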