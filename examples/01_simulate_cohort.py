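"""Generate a synthetic ageing cohort and inspect its tables.

The generator emulates the derived data of a single-wave brain-imaging
cohort: hemispheric values for 34 paired cortical regions (surface area,
volume, thickness) and 5 paired white-matter tracts (fractional
anisotropy), a 13-test cognitive battery with a hierarchical
general-intelligence structure, and four childhood-SES indicators.
"""

import neuroasym as na

config = na.default_config(seed=1)
cohort = na.generate_cohort(config)

print(f"participants: {config.n_participants}")
print(f"thickness rows (participant x region x hemisphere): "
      f"{len(cohort.regional['thickness'].data)}")
print(cohort.regional["thickness"].data.head())
print()
print("cognitive battery (first rows):")
print(cohort.cognitive.iloc[:3, :6])
print()
print("SES indicators:")
print(cohort.ses.head(3))
# The tables are what a study would distribute; cohort.truth additionally
# carries the generating latent quantities (g, instability, SES factor)
# so that simulation studies can measure recovery.
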