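# tmea — tumor-microenvironment archetype analysis for imaging mass cytometry

`tmea` is a Python library for spatially resolved single-cell analysis of
imaging-mass-cytometry (IMC) cohorts — ~35 protein channels at ~1 µm
resolution over tumor tissue — aimed at relating the architecture of the
melanoma tumor microenvironment (TME) to immunotherapy response. It is
written for computational biologists who start from segmented images (or
pre-extracted cell tables) plus clinical annotations and want a tested,
deterministic implementation of the full chain:

1. **Quantification** — per-cell marker means from channel stacks + label
   masks; background correction against *decoy cells* (pseudo-cells sampled
   from cell-free regions); per-channel positive-cell calling at FDR 0.01
   against the decoy null; cross-ROI normalization on positive-cell medians.
2. **Phenotyping** — two-level cell typing via a batch self-organizing map
   plus Louvain clustering of node profiles, annotated by marker gating into
   4 main types and 20 subtypes (T-cell subsets, B cells, monocytes MC1–MC6,
   stroma S1–S5, tumor T1–T4).
3. **Spatial interactions** — for each cell-type pair in each image, the
   neighboring-pair count within 20 µm is tested against a label-permutation
   null:

   P_AB = 1 if C_obs = 0, else ( #{C_perm ≥ (≤) C_obs} + 1 ) / (N_perm + 1),

   with ≥ for interaction and ≤ for avoidance, N_perm = 1000, calls at
   P ≤ 0.01.
4. **Communities** — Louvain subunits of the 20 µm graph, clustered across
   samples into recurring multicellular community types.
5. **Heterogeneity** — Shannon entropy H = −Σ_c P_c log₂ P_c of subtype
   frequencies on 3×1000-cell subsamples, compared across regions and
   response groups by Wilcoxon rank-sum.
6. **Archetypes** — cell types enriched between responders and
   nonresponders (|log₂FC| ≥ 1.2, BH p ≤ 0.05, density ≥ 1%) feed
   complete-linkage clustering of invasive-margin ROIs into six TME
   archetypes (H1–H3 immune-hot, C1–C3 immune-cold); patients are voted
   hot/cold over their ROIs (ties → hot), with ROI accuracies, objective
   response rates, and exact binomial CIs for TLS enrichment.
7. **Prognostic score** — a fixed 24-gene signature (20 up, 4 down); score =
   mean(up)/mean(down) per sample, evaluated by ROC/AUC, automatic cut-point
   Kaplan–Meier with log-rank, and age-adjusted Cox models.

A first-class synthetic-cohort generator (`tmea.generate_cohort`) plants
known subtypes, spatial motifs, archetype compositions, survival contrasts
and expression signatures, so every stage is testable end-to-end without any
data download.

## Worked example

```python
import tmea

cohort = tmea.generate_cohort(tmea.CohortConfig(n_patients=6, cells_per_roi=500, seed=1))
cells, model = tmea.phenotype_cells(cohort.cells, seed=0)
print(tmea.matched_accuracy(cells["true_subtype"], cells["subtype"]))
densities = tmea.compute_densities(cells)
```

Running `python examples/03_phenotype.py` (the script around the snippet
above) prints:

```
planted-subtype recovery (Hungarian matched): 98.0%

cells per recovered main type:
main_type
tumor       5270
lymphoid    2777
myeloid     2738
stromal     1215
```

98% of 12 000 cells are assigned their planted subtype from marker
intensities alone; the density table rows sum to 1 per image and feed the
archetype stage. `python examples/07_prognostic_score.py` evaluates the
24-gene score on a 20-patient cohort:

```
mean score: hot 1.89, cold 0.96
AUC hot vs cold: 1.000 (95% CI 1.000-1.000)
cut-point 0.99: 9 low vs 11 high, log-rank p = 0.0095 (exploratory (maximally selected cut-point))
age-adjusted Cox HR per unit score: 0.223 (95% CI 0.051-0.967)
```

Hot patients carry higher scores (the signature is planted at ±2 log₂ fold
change), the score separates the groups perfectly at this effect size, and a
higher score reduces the hazard (HR < 1). The cut-point p-value is labelled
exploratory because the threshold maximizes that statistic by construction.

The `examples/` directory holds one short script per capability
(simulation, quantification, phenotyping, spatial interactions,
communities + entropy, archetypes, prognostic score); each builds a small
input, runs the method and explains its printout.

## Scope

Segmentation, staining/acquisition, differential-gene discovery and
external-cohort harmonization are out of scope: masks, clinical labels, TLS
flags and the signature gene lists are inputs. See `docs/methods.md` for
models, defaults, design decisions and limitations.
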