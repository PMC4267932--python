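"""Genotype-specific trait trajectories implied by a slope QTL.

Takes population-level numbers for earlywood percentage - mean 56.3%,
trend -3.0 %/yr - plus a 0.23 deg/yr marker effect on the transformed
(arcsine-square-root, degrees) trend, and projects the two genotype
classes of a 1:1-segregating marker five years ahead.  Also reports each
effect as a percentage of its reference quantity.
"""

import numpy as np

from funcqtl import report

traj = report.predict_genotype_trajectories(
    pop_mean_pct=56.3,
    pop_trend_pct_per_yr=-3.0,
    qtl_slope_effect_deg_per_yr=0.23,
    start_age=9,
    horizon_yr=5,
)

print("cambial age:      ", traj.ages.astype(int).tolist())
print("population EP (%):", np.round(traj.population_pct, 1).tolist())
print("band present (%): ", np.round(traj.present_pct, 1).tolist())
print("band absent (%):  ", np.round(traj.absent_pct, 1).tolist())

p0 = 0.563
dT_dp = (180 / np.pi) / (2 * np.sqrt(p0 * (1 - p0)))
pop_slope_deg = -0.030 * dT_dp
ratios = report.effect_size_ratios(
    {"EP slope": 0.23, "EWD mean": 7.7, "EFWr mean": 0.27},
    {"EP slope": pop_slope_deg, "EWD mean": 327.7, "EFWr mean": 32.7},
)
print("\neffect sizes relative to their references:")
for k, v in ratios.items():
    print(f"  {k}: {v:.1f}%")

print(
    "\nBoth genotype classes decline, but the band-absent class matures"
    "\nfaster: by age 14 it reaches ~40.3% earlywood vs ~42.2% for band"
    "\npresent. The slope effect is ~13% of the population trend on the"
    "\ntransformed scale; intercept effects are 0.8-2.3% of trait means."
)
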