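"""Generate a small synthetic IMC cohort with planted structure.

Every downstream example starts from a cohort like this: per-cell marker
intensities with known true subtypes, per-ROI metadata with true archetypes,
a bulk expression matrix and survival times.
"""

import tmea

config = tmea.CohortConfig(n_patients=6, cells_per_roi=500, seed=1)
cohort = tmea.generate_cohort(config)

print(f"patients: {config.n_patients}, ROIs: {len(cohort.meta)}, "
      f"cells: {len(cohort.cells)}")
print("\nROIs per region/response:")
print(cohort.meta.groupby(["region", "response"]).size())
print("\nplanted archetypes:")
print(cohort.meta.drop_duplicates("patient")["archetype"].value_counts())
print("\nfirst cells (marker columns truncated):")
print(cohort.cells[["cell_id", "image_id", "x_um", "y_um", "CD3", "CD20",
                    "true_subtype"]].head())
# The archetype of each patient drives both the subtype mix of its ROIs and
# the hot/cold label that the survival and expression modules use.
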