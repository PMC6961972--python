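"""Score fluctuating asymmetry under both weighting schemes.

Equal contribution: every region counts the same regardless of size
(deviation from the sample's directional mean, taken absolute, divided by
the participant's bilateral mean, averaged over regions).  Proportional
contribution: hemispheric totals are differenced first, so large regions
dominate.  The two scores measure different things and correlate weakly.
"""

import neuroasym as na

cohort = na.generate_cohort(na.default_config(seed=1))
paired = na.pair_hemispheres(cohort.regional["thickness"])

equal = na.fluctuating_asymmetry_equal(paired)
proportional = na.fluctuating_asymmetry_proportional(paired)

print("equal-contribution thickness asymmetry (dimensionless):")
print(equal.scores.describe().round(4))
print()
comparison = na.compare_methods(equal, proportional)
print(f"equal vs proportional Pearson r = {comparison.r:.3f} "
      f"(p = {comparison.p:.3g}, n = {comparison.n})")
print()
# Directional asymmetry: one-sample t-test of L-R against zero per region.
ttests = na.directional_ttests(paired)
print("regions with significant directional asymmetry (p < .05):",
      (ttests["p"] < 0.05).sum(), "of", len(ttests))
# P-FIT subset score: same procedure restricted to the 10 frontoparietal
# regions, with centering recomputed within the subset.
pfit = na.subset_scores(paired, na.default_partition(), "pfit", "equal")
print("P-FIT subset uses", len(pfit.regions_used), "regions")
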