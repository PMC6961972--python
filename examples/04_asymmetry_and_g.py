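"""Relate global asymmetry scores to g and compare effect sizes.

The three cortical asymmetry scores (z-scored, freely correlated) each
get a structural path to g.  Nested chi-square difference tests then ask
whether the thickness effect differs from the surface-area and volume
effects, mirroring the equality-constraint comparisons of the original
analysis.
"""

import neuroasym as na
from neuroasym.pipeline import effect_size_difference, g_model_data

cohort = na.generate_cohort(na.default_config(seed=1))
scores = {}
for metric in ("surface_area", "volume", "thickness"):
    paired = na.pair_hemispheres(cohort.regional[metric])
    scores[metric] = na.fluctuating_asymmetry_equal(paired).scores

spec, result = na.global_asymmetry_model(cohort.cognitive, scores)
print("standardized paths to g:")
for metric in scores:
    beta = result.std_estimate("path", "g", f"asym_{metric}")
    se = result.se("path", "g", f"asym_{metric}")
    print(f"  {metric:<13} beta = {beta:+.3f} (SE {se:.3f})")

data = g_model_data(cohort.cognitive,
                    {f"asym_{m}": s for m, s in scores.items()})
for other in ("asym_surface_area", "asym_volume"):
    cmp_ = effect_size_difference(spec, result, data, ("asym_thickness", other))
    print(f"thickness vs {other[5:]:<13} d_chisq = {cmp_.d_chisq:.2f} "
          f"(1 df), p = {cmp_.p:.3f}")
# A significant difference means the thickness effect size cannot be
# equated with the other metric's effect without worsening model fit.
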