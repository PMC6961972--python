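"""Childhood-SES mediation and the P-FIT regional contrast.

First: does thickness asymmetry mediate the association between a latent
childhood-SES factor (four indicators) and g?  The attenuation percentage
is 100 x indirect / total on standardized paths.  Second: are the P-FIT
(frontoparietal) regions' asymmetries more strongly related to g than the
remaining 24 regions'?  Each metric's P-FIT and non-P-FIT paths are
equated in turn and the fit loss tested on 1 df.
"""

import neuroasym as na
from neuroasym.pipeline import mediation_model, pfit_model

cohort = na.generate_cohort(na.default_config(seed=1))
part = na.default_partition()

thickness = na.fluctuating_asymmetry_equal(
    na.pair_hemispheres(cohort.regional["thickness"])).scores
med = mediation_model(cohort.cognitive, cohort.ses, thickness)
print("SES -> thickness asymmetry (a):", round(med.a_std, 3))
print("thickness asymmetry -> g (b):  ", round(med.b_std, 3))
print("direct SES -> g (c'):          ", round(med.c_prime_std, 3))
print(f"indirect = {med.indirect_std:+.4f}, attenuation = "
      f"{med.attenuation_pct:.2f}% (p = {med.indirect_p:.3f})")
print()

subset_map = {}
for metric in ("surface_area", "volume", "thickness"):
    paired = na.pair_hemispheres(cohort.regional[metric])
    for subset in ("pfit", "non_pfit"):
        subset_map[f"asym_{metric}_{subset}"] = na.subset_scores(
            paired, part, subset, "equal").scores
free_fit, comparisons, table = pfit_model(cohort.cognitive, subset_map)
print(table.round(3).to_string(index=False))
for metric, cmp_ in comparisons.items():
    print(f"{metric}: equating P-FIT and non-P-FIT paths, "
          f"d_chisq = {cmp_.d_chisq:.2f}, p = {cmp_.p:.3f}")
# Non-significant contrasts mean the frontoparietal subset is not more
# strongly tied to g than the rest of the cortex.
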