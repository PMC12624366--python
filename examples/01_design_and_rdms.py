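"""Build the oriented stimulus design and compare feature models with RDMs.

90 base touch videos are expanded into 360 stimuli (left/right hand x
self/other perspective).  Each stimulus carries categorical sensory labels
and continuous affective ratings; the valence score is the first principal
component of the per-video pleasant/unpleasant categorisation percentages.
Feature models are compared by Spearman-correlating their stimulus x
stimulus dissimilarity matrices (lower triangles).
"""

import touchdecode as td

design = td.build_design(90, seed=1)
print(f"design: {len(design)} stimuli, "
      f"{design['base_video_id'].nunique()} base videos, "
      f"{design['object_type'].nunique()} object types, "
      f"{design['material'].nunique()} materials, "
      f"{design['touch_type'].nunique()} touch types")

for col in ("object_type", "material", "touch_type"):
    print(f"  chance level for {col}: {100 / design[col].nunique():.1f}%")

# RDM comparison: how much do the feature models overlap?
rdms = {
    "valence": td.feature_rdm(design["valence"], "continuous"),
    "threat": td.feature_rdm(design["threat"], "continuous"),
    "pain": td.feature_rdm(design["pain"], "continuous"),
    "material": td.feature_rdm(design["material"], "categorical"),
    "contact_agent": td.feature_rdm(design["contact_agent"], "categorical"),
}
print("\nSpearman correlations between feature RDMs "
      "(1 = identical stimulus geometry, 0 = unrelated):")
names = list(rdms)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        rho = td.rdm_spearman(rdms[a], rdms[b])
        print(f"  {a:14s} vs {b:14s} rho = {rho:+.3f}")
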