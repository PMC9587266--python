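# Methods

`tmea` re-implements, as a tested library, a spatial single-cell analysis of
imaging-mass-cytometry (IMC) melanoma cohorts: from segmented multichannel
images to background-corrected cell tables, a two-level cell-type taxonomy,
interaction/avoidance maps, multicellular communities, composition entropy,
tumor-microenvironment (TME) archetypes with hot/cold patient calls, and an
archetype-derived prognostic gene score. This note records the models,
defaults and design decisions; the README shows the surface.

## Quantification

Per-cell marker means are extracted by overlaying integer label masks on the
channel stacks (`skimage.measure.regionprops`); centroids are unweighted
pixel centroids in µm at a fixed 1 µm/px raster (Hyperion ablation;
configurable).

**Decoy cells.** The noise null per channel comes from pseudo-cells: disks of
radius 5 µm rejection-sampled uniformly over background pixels at least
2 µm + radius away from any cell mask, mutually non-overlapping (default
500 per image). "Background region" is under-specified in the underlying
protocol; uniform cell-free disks are the assumption-free reading.

**Correction and calling.** Corrected mean = max(0, raw − mean of decoy
means) per channel — intensities are nonnegative by construction, hence the
clip. Positive cells are called per (image, channel) from empirical
p-values p = (1 + #{decoy ≥ cell}) / (1 + n_decoys) with Benjamini–Hochberg
at FDR 0.01. Note the granularity constraint: the smallest achievable p is
1/(n_decoys+1), so with the default 500 decoys a channel whose positive
fraction is below roughly (n_decoys+1)·FDR/n_cells cannot be called at all;
raise `n_decoys` when rare positives matter.

**Cross-ROI normalization** multiplies each (image, channel) by
(cohort median of positive-cell values)/(image median of positive-cell
values). The median (rather than mean) is robust to the heavy right tails
typical of IMC intensities; images or channels without positives pass
through with factor 1. The procedure is idempotent up to floating error.

## Phenotyping

Marker values are clipped at the per-marker 99th percentile
(linear-interpolation definition) and min–max scaled to [0, 1]. Clustering
follows the SOM-then-graph recipe: a batch self-organizing map (default
10×10 grid, 15 epochs, Gaussian neighborhood decaying linearly from
max(grid)/2 to 0.5, codebook seeded from sampled cells) quantizes cells into
nodes; the mean profile of each occupied node is then clustered by a
kNN graph with Jaccard edge weights and Louvain modularity optimization
(networkx, seeded).

Two choices here matter and were fixed after the node-count arithmetic
proved the naive variants wrong on synthetic blobs:

* **Mutual-kNN restriction.** The SOM allocates nodes in proportion to cell
  density, so a subtype at 2% of cells may own a single node whose k nearest
  nodes all belong to a large unrelated population. Keeping only reciprocated
  kNN edges lets such a node stay a singleton metacluster instead of being
  absorbed; absorption destroys the gating stage below.
* **k = 5 for node clustering in the pipeline** (the standalone function
  defaults to 30). With ~100 nodes and up to 9 expected clusters per stage,
  a large k forces cross-cluster edges. Over-splitting is harmless — several
  metaclusters may share a gated name — but merging is not.

**Two stages, then gating.** Stage 1 clusters all cells on the 20 lineage
markers and gates each metacluster into lymphoid / myeloid / other by its
elevated markers (scaled mean ≥ 0.5, configurable): CD45 with CD3 or CD20 →
lymphoid; any of CD14/CD16/CD68/CD11c/CD11b → myeloid. Stage 2 re-clusters
each group on all markers except the immune-checkpoint set and names the
20 subtypes by an ordered rule table (e.g. CD4+CD8a → DPT before CD4 → CD4+T;
HLA-DR splits the antigen-presenting monocytes MC4–MC6 from the
HLA-DR− suppressive MC1–MC3; "other" resolves into stromal S1–S5 vs tumor
T1–T3 by structural vs tumor markers). Metaclusters elevated on no rule
marker fall to the non-classified tumor subtype T4. The 0.5 threshold is a
reproducible surrogate for visual heatmap annotation.

Cell-type density is the count of a type over all cells of the image.

## Spatial analysis

Cells within 20 µm centroid distance (inclusive — the boundary convention is
ours) are neighbors; the undirected pair count C_obs for an ordered type pair
is compared against N_perm = 1000 label shuffles over the fixed graph:
p = (#{C_perm ≥ (≤) C_obs} + 1)/(N_perm + 1) for interaction (avoidance),
and p = 1 exactly when C_obs = 0. Pairs with an absent type are skipped
rather than reported at p = 1, which would otherwise inflate "no avoidance"
summaries. Cohort summaries report the fraction of images significant at
α = 0.01 per pair; regional structure uses Spearman correlation of densities
across images; proximity uses per-source-cell nearest distance to the target
type within the same image.

The permutation p-values are valid but discrete: under the null the
attainable rejection rate at α = 0.01 is slightly below nominal (ties in the
count distribution), which the type-I simulations show as rates near
0.006–0.010.

## Communities

Louvain on the 20 µm graph partitions each image into spatial subunits;
communities under 10 cells are merged into the neighbor they share most
edges with (or flagged unassigned). The default resolution is 0.5: at 1.0,
modularity optimization splits a single dense aggregate (σ ≈ 15 µm,
100–200 cells) of a geometric graph into arbitrary halves, which misstates
the motif scale this analysis targets. Community compositions, min–max
normalized per subtype across all communities pooled over images, are
clustered by the same kNN-Jaccard-Louvain machinery into recurring community
types; pick `k_neighbors` near the expected recurrence count of a community
type.

## Heterogeneity

H = −Σ P_c log2 P_c over occurring subtype frequencies, on three subsamples
of 1000 cells each (without replacement; smaller samples use all cells and
replicates coincide), averaged. Plug-in entropy is biased low by
O(types/n); at n = 1000 and 20 subtypes the bias is ≪ 0.02 bits. Group
contrasts use the two-sided Wilcoxon rank-sum test (exact null when the
pooled sample is untied and ≤ 40 values) with BH adjustment across the
contrasts run together.

## Archetypes

Cell types differentially abundant between responders and nonresponders are
selected by |log2FC| ≥ 1.2 (means with ε = 1e-6 pseudocount), BH-adjusted
Wilcoxon p ≤ 0.05, and overall density ≥ 1%. Invasive-margin ROIs are
clustered on z-scaled selected densities (Euclidean, complete linkage, cut
at k = 6). Archetypes are named by their dominant positively-enriched type
(B/CD4+T → H1-like, MC4 → H2, CD8+T → H3, CAIX+ tumor → C1, MC2 → C2,
nothing → C3) and categorized hot iff any of {B, CD4+T, CD8+T, MC4} has a
positive mean z-score — a reproducible surrogate for composition-based
judgment, with a config override for manual fidelity. Patients are voted
hot/cold over their IM ROIs with exact ties called hot. Core-tumor ROIs are
not archetyped. Evaluation helpers compute ROI accuracies, per-category
objective response rates, Clopper–Pearson exact binomial CIs for
TLS-by-archetype fractions, and per-type age-adjusted Cox models
(lifelines; non-convergence flagged, not fatal).

## Prognostic score

Score = mean(20 up genes)/mean(4 down genes) per sample. The gene lists are
fixed inputs shipped with the package; re-deriving them (differential
expression against a curated immuno-oncology panel) is out of scope. The
expression scale for the ratio is ambiguous in the source description; the
default computes it on the provided log2 scale after a global shift to ≥
0.01, with `linear_scale=True` to exponentiate first. Evaluation: AUC by the
Mann–Whitney definition with a stratified bootstrap percentile CI (2000
reps); an automatic cut-point maximizing the log-rank statistic over
observed scores within the 10th–90th percentile band with ≥ 5 subjects per
side — the resulting log-rank p is labelled exploratory, since maximally
selected statistics are anti-conservative by construction (deliberately not
corrected, mirroring common practice); and an age-adjusted Cox model.

## Synthetic cohorts

The generator emulates the study conditions end to end: 20 patients (half
responders), 2 core-tumor + 2 invasive-margin ROIs each, ~1000 cells per
400×400 µm ROI, 35 channels. Each subtype's profile has its defining markers
at 10 counts/px and all others at 0.02, over a Poisson background of
0.1 counts/px; cell means are Poisson disk-averages (radius 5 µm, area
~78 px), identical in distribution whether or not images are rendered.
Cells are placed in Gaussian clusters (σ = 15 µm, ~80 cells, centers
uniform, 4 µm minimum spacing). Six archetype composition vectors (three
hot, three cold) differ only in the six response-discriminating types
(B, CD4+T, CD8+T, MC4, MC2, CAIX+ tumor), all other subtypes held at 2%
with the non-classified tumor fraction absorbing the remainder — so the
differential-abundance stage has an exactly known target. Responders carry
hot archetypes; all ROIs of a patient share one archetype. Survival is
Weibull (shape 1) with hot/cold scales 60/20 months and exponential
censoring (scale 120 months); bulk expression plants ±2 log2 fold change
with 0.5 SD noise on the 24 signature genes over ≥ 100 null genes.

What the generator does **not** emulate: optical spillover and channel
crosstalk, nucleus/membrane compartments and real morphologies, segmentation
errors, marker co-expression gradients, mixed-archetype patients, and
batch-varying backgrounds. Passing recovery tests therefore demonstrates
correctness of the computational chain on its stated model, not performance
on real IMC data.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full pipeline on 20 patients ×
4 ROIs × 800 cells (64k cells), the permutation null on 100 images × 300
cells (≥ 2000 tests at N_perm = 500), and community recovery on 5 planted
two-motif images — sizes chosen as the smallest at which the cohort-level
statistics are stable.
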