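"""Two-step multilevel LASSO analysis of a simulated longitudinal trait.

Step 1 fits each tree's measurements to a straight line in centred time,
giving latent intercept (tree-level mean) and slope (annual change)
traits.  Step 2 screens the markers with a cross-validated lasso on each
latent trait and attaches four uncertainty measures per marker: the
Bonferroni-adjusted single-marker re-test (Single-p), the multi-split test
(MST-p), the covariance test (COV-p) and the stability selection
probability (SSP).  Markers are then classified as suggestive/significant
QTL and the explained latent-trait variance (H2) is reported.
"""

import numpy as np

from funcqtl import inference, report, synthetic, trends
from funcqtl.report import DatasetProfile

# --- simulate: one intercept QTL and one slope QTL among 100 markers
genotypes, _ = synthetic.simulate_pedigree_genotypes(300, [(40, 12.0), (40, 12.0)], 20, seed=2024)
beta = np.zeros(100)
gamma = np.zeros(100)
beta[17] = 2.5
gamma[91] = 0.6
params = synthetic.ep_default_params(100, beta=beta, gamma=gamma, seed=91)
phenotypes, _ = synthetic.simulate_longitudinal_traits(genotypes, params, trait_id="EP")

# --- step 1: latent traits
latent = trends.build_latent_traits(phenotypes)
kept = latent[latent["retained"]]
print(f"latent traits for {len(kept)} of {len(latent)} trees "
      f"(excluded: fewer than 4 of 9 rings observed)")

X = genotypes.codes[[genotypes.individuals.index(i) for i in kept["individual_id"]]]

profile = DatasetProfile(
    p_markers=100,
    ssp_suggestive=inference.ssp_threshold(100, 10, 2.0),
    ssp_significant=inference.ssp_threshold(100, 10, 1.0),
)
print(f"SSP thresholds for this panel: suggestive {profile.ssp_suggestive}, "
      f"significant {profile.ssp_significant}")

for target, column in [("intercept", "mu0_hat"), ("slope", "mu1_hat")]:
    y = kept[column].to_numpy()
    tab = inference.build_test_report(
        X, y, marker_ids=genotypes.markers,
        n_splits=30, ssp_config=inference.SSPConfig(n_subsamples=200), seed=5,
    )
    calls = report.classify_qtl(tab, None, profile, trait_id="EP", target=target)
    hits = [c for c in calls if c.level != "none"]
    print(f"\n=== {target} trait ===")
    for c in hits:
        row = tab[tab["marker"] == c.marker].iloc[0]
        print(f"  {c.marker}: {c.level:11s} lasso effect {row.lasso_effect:+.2f}, "
              f"single_p={row.single_p:.3g}, cov_p={row.cov_p:.3g}, ssp={row.ssp:.2f}")
    effects = {
        i: e for i, e in enumerate(tab["lasso_effect"]) if e != 0 and calls[i].level != "none"
    }
    h2 = report.h2_qtl(effects, X, y)
    print(f"  H2 (latent-{target} variance explained by called QTL): {h2:.2f}")

print(
    "\nThe planted markers (M0018 for the mean, M0092 for the trend) should"
    "\nbe the ones called; effects are on the transformed degree scale."
)
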