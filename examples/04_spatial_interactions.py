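"""Cell-cell interaction/avoidance mapping by label permutation.

Cells within 20 µm are neighbors; the observed neighboring-pair count per
type pair is compared with a label-shuffled null. Low p_interaction means
the two types touch more often than chance; low p_avoidance, less often.
"""

import tmea

cohort = tmea.generate_cohort(tmea.CohortConfig(n_patients=4, cells_per_roi=600, seed=2))
cells, _ = tmea.phenotype_cells(cohort.cells, seed=0)

frames = []
for image_id, roi in cells.groupby("image_id"):
    graph = tmea.build_graph(roi, threshold_um=20.0, image_id=image_id)
    res = tmea.permutation_test(graph, roi["subtype"].to_numpy(),
                                n_perm=500, seed=7)
    frames.append(res)

import pandas as pd

results = pd.concat(frames, ignore_index=True)
freq = tmea.summarize_frequency(results, images=list(cells["image_id"].unique()))
top = freq.sort_values("frac_interaction", ascending=False).head(8)
print("pairs interacting in the largest fraction of images:")
print(top.to_string(index=False))

dist = tmea.nearest_distance(cells, "CD8+T", "MC4")
print(f"\nmedian nearest CD8+T -> MC4 distance: {dist['distance_um'].median():.1f} um "
      f"({dist.attrs['n_excluded']} source cells had no target in their image)")
# Because cells are placed in mixed-composition clusters, frequent subtypes
# co-occur spatially and show high interaction frequencies.
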