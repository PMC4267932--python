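"""One-step Bayesian mixed-model QTL analysis of the same simulated trait.

Fits the full longitudinal model - population trend, per-tree random
intercepts and slopes, and spike-and-slab marker effects on both - by
Gibbs sampling, then selects markers with the Bayesian false discovery
rate rule on the sorted local FDRs (LFDR = 1 - PIP).
"""

import numpy as np

from funcqtl import blmm, synthetic

genotypes, _ = synthetic.simulate_pedigree_genotypes(300, [(40, 12.0), (40, 12.0)], 20, seed=2024)
beta = np.zeros(100)
gamma = np.zeros(100)
beta[17] = 2.5
gamma[91] = 0.6
params = synthetic.ep_default_params(100, beta=beta, gamma=gamma, seed=91)
phenotypes, truth = synthetic.simulate_longitudinal_traits(genotypes, params, trait_id="EP")

draws, summary = blmm.gibbs_sampler(
    phenotypes, genotypes, n_iter=3000, burn_in=1000, seed=11
)

print("posterior population trend: "
      f"alpha0 = {summary.alpha0:.2f} deg, alpha1 = {summary.alpha1:.2f} deg/yr")
print("random-effect covariance Sigma =\n", np.round(summary.Sigma, 2))
print(f"residual variance sigma0^2 = {summary.sigma0_sq:.2f}\n")

m = summary.markers
for target in ("intercept", "slope"):
    lfdr = m[f"lfdr_{target}"].to_numpy()
    sel, bfdr = blmm.bfdr_select(lfdr, alpha=0.05)
    print(f"{target}: BFDR-selected at alpha=0.05 -> "
          f"{list(m['marker'].iloc[sel])} (set BFDR {bfdr:.3f})"
          if sel.size else f"{target}: no marker passes BFDR < 0.05")
    top = m.nlargest(3, f"pip_{target}")
    for _, r in top.iterrows():
        print(f"   {r['marker']}: PIP {r[f'pip_{target}']:.2f}, "
              f"posterior-mean effect {r[f'effect_{target}']:+.2f}")

print(
    "\nPIP is the posterior probability a marker has a nonzero effect;"
    "\nthe planted markers M0018 (mean) and M0092 (trend) should carry"
    "\nPIP near 1 while everything else stays low."
)
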