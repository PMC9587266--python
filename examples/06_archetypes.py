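"""TME archetypes: differential abundance, clustering, hot/cold, voting.

Selects the cell types that separate responders from nonresponders, clusters
invasive-margin ROIs into six archetypes, categorizes archetypes hot/cold,
and votes patients — then scores the classification against the true
response labels.
"""

from sklearn.metrics import adjusted_rand_score

import tmea

cohort = tmea.generate_cohort(tmea.CohortConfig(n_patients=20, cells_per_roi=800, seed=11))
cells, _ = tmea.phenotype_cells(cohort.cells, seed=0)
densities = tmea.compute_densities(cells)
meta = cohort.meta.set_index("image_id")
im = meta[meta.region == "IM"]

da = tmea.differential_abundance(densities.loc[im.index], im["response"])
print("selected cell types (|log2FC| >= 1.2, adj p <= 0.05, density >= 1%):")
print(da[da.passes_selection][["cell_type", "log2fc", "p_adj"]].round(3).to_string(index=False))

selected = list(da.loc[da.passes_selection, "cell_type"])
model = tmea.cluster_archetypes(densities.loc[im.index], selected, k=6)
print(f"\narchetype recovery vs planted labels: "
      f"ARI = {adjusted_rand_score(im['archetype'], model.roi_labels):.2f}")
print("hot/cold categories:", model.category)

votes = tmea.vote_patients(
    cohort.meta.assign(archetype=cohort.meta["image_id"].map(model.roi_labels)),
    model.category)
resp = cohort.meta.drop_duplicates("patient").set_index("patient")["response"]
metrics = tmea.classification_metrics(
    model.roi_labels.map(model.category), im["response"],
    votes.set_index("patient")["voted_category"], resp)
print(f"\nresponder ROIs called hot: {metrics['responder_roi_accuracy_pct']:.1f}%")
print(f"nonresponder ROIs called cold: {metrics['nonresponder_roi_accuracy_pct']:.1f}%")
print(f"ORR hot patients: {metrics['orr_hot_pct']:.1f}%, "
      f"cold patients: {metrics['orr_cold_pct']:.1f}%")
# On this planted cohort responders carry hot archetypes by construction,
# so accuracies approach 100%; real cohorts show exceptions.
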