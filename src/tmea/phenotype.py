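"""Two-level cell phenotyping: SOM metaclustering + graph clustering + gating.

Stage 1 clusters all cells on the 20 lineage markers into main types
(lymphoid / myeloid / other); stage 2 re-clusters each main type on all
markers except the immune-checkpoint set and names the 20 subtypes by a
marker-gating rule table applied to metacluster mean profiles ("elevated" =
scaled mean >= a threshold on the [0, 1] preprocessed scale). The clustering
itself follows the FlowSOM-then-Phenograph recipe: a self-organizing map
quantizes cells into nodes, and Louvain on a Jaccard-weighted kNN graph of
node mean profiles yields metaclusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .panel import DEFAULT_PANEL, MarkerPanel, SUBTYPE_ONTOLOGY

__all__ = [
    "preprocess",
    "BatchSOM",
    "som_metacluster",
    "graph_cluster_nodes",
    "gate_main_type",
    "gate_subtype",
    "phenotype_cells",
    "compute_densities",
    "ClusterModel",
]

#: Scaled-mean threshold above which a marker counts as "elevated" in gating.
ELEVATED_THRESHOLD = 0.5


def preprocess(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Clip each marker at its 99th percentile (linear-interpolation
    definition) then min–max normalize to [0, 1]; constant markers map to 0."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 cells")
    p99 = np.percentile(x, 99, axis=0)
    x = np.minimum(x, p99[None, :])
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    rng_ = hi - lo
    rng_[rng_ == 0] = 1.0  # constant marker -> zeros
    return (x - lo[None, :]) / rng_[None, :]


class BatchSOM:
    """Batch-trained self-organizing map on a rectangular grid.

    Gaussian neighborhood with radius decaying linearly from max(grid)/2 to
    0.5 over the epochs; codebook initialized from randomly sampled data
    points. Deterministic under a fixed seed.
    """

    def __init__(self, grid: tuple[int, int] = (10, 10), epochs: int = 15, seed: int = 0):
        if grid[0] * grid[1] < 2:
            raise ValueError("SOM grid needs at least 2 nodes")
        self.grid = grid
        self.epochs = epochs
        self.seed = seed
        self.codebook: np.ndarray | None = None
        rows, cols = grid
        g = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
        self._grid_d2 = ((g[:, None, :] - g[None, :, :]) ** 2).sum(-1)

    def fit(self, x: np.ndarray) -> "BatchSOM":
        x = np.asarray(x, dtype=float)
        if len(x) == 0:
            raise ValueError("cannot fit a SOM on empty input")
        rng = np.random.default_rng(self.seed)
        n_nodes = self.grid[0] * self.grid[1]
        self.codebook = x[rng.integers(len(x), size=n_nodes)].astype(float).copy()
        sigma0 = max(self.grid) / 2.0
        for ep in range(self.epochs):
            frac = ep / max(1, self.epochs - 1)
            sigma = sigma0 + frac * (0.5 - sigma0)
            bmu = self.predict(x)
            h = np.exp(-self._grid_d2 / (2 * sigma**2))  # (nodes, nodes)
            w = h[bmu]  # (n, nodes) neighborhood weight of each cell to each node
            denom = w.sum(axis=0)
            num = w.T @ x
            upd = denom > 1e-12
            self.codebook[upd] = num[upd] / denom[upd, None]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Index of the nearest codebook node (Euclidean) per row of x."""
        x = np.asarray(x, dtype=float)
        # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2; ||x||^2 constant per row
        d2 = -2.0 * (x @ self.codebook.T) + (self.codebook**2).sum(axis=1)[None, :]
        return d2.argmin(axis=1)


def som_metacluster(
    values: np.ndarray, grid: tuple[int, int] = (10, 10), seed: int = 0, epochs: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Train a batch SOM and assign each cell to its nearest node.

    Returns (node assignment per cell, codebook)."""
    som = BatchSOM(grid=grid, epochs=epochs, seed=seed).fit(values)
    return som.predict(values), som.codebook


def graph_cluster_nodes(
    node_means: np.ndarray, k_neighbors: int = 30, seed: int = 0, resolution: float = 1.0
) -> np.ndarray:
    """Phenograph-style clustering of node mean profiles: kNN graph
    (Euclidean), Jaccard edge weights on shared neighborhoods, Louvain.

    Edges are kept only between mutual nearest neighbors: a node whose
    k-neighborhood is not reciprocated (e.g. the sole SOM node of a rare
    population, surrounded by a dense unrelated blob) stays a singleton
    metacluster instead of being absorbed. Returns contiguous labels from 0,
    deterministic under the seed.
    """
    x = np.asarray(node_means, dtype=float)
    n = len(x)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_nodes={n}")
    if n == 1:
        return np.zeros(1, dtype=int)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = [set(row) for row in idx]  # includes self
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i or g.has_edge(i, j) or i not in neigh[j]:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                g.add_edge(i, j, weight=w)
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed,
                                             resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for li, members in enumerate(comms):
        labels[members] = li
    return labels


# ---------------------------------------------------------------------------
# gating rules


def gate_main_type(elevated: set[str]) -> str:
    """Main type from the elevated lineage markers of a metacluster."""
    if "CD45" in elevated and ({"CD3", "CD20"} & elevated):
        return "lymphoid"
    if {"CD14", "CD16", "CD68", "CD11c", "CD11b"} & elevated:
        return "myeloid"
    return "other"


#: Ordered gating rules per main type: first rule whose markers are all
#: elevated wins. 'other' covers both stromal and tumor subtypes.
_SUBTYPE_RULES: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "lymphoid": [
        ("DPT", ("CD4", "CD8a")),
        ("Treg", ("CD4", "FoxP3")),
        ("CD4+T", ("CD3", "CD4")),
        ("CD8+T", ("CD3", "CD8a")),
        ("B", ("CD20",)),
        ("B", ("CD19",)),
    ],
    "myeloid": [
        ("MC4", ("HLA-DR", "CD11c")),
        ("MC6", ("HLA-DR", "CD68")),
        ("MC5", ("HLA-DR",)),
        ("MC1", ("IDO",)),
        ("MC2", ("VEGF",)),
        ("MC3", ("CAIX",)),
    ],
    "other": [
        ("S1", ("CollagenI",)),
        ("S2", ("FAP",)),
        ("S3", ("PDGFRb",)),
        ("S4", ("aSMA",)),
        ("S5", ("Vimentin",)),
        ("T1", ("CAIX",)),
        ("T2", ("Ki67",)),
        ("T3", ("VEGF",)),
    ],
}


def gate_subtype(elevated: set[str], main_type: str) -> str:
    """Subtype name from the elevated markers of a metacluster within one
    main type; profiles elevated on no rule marker fall to T4 (n.c.)."""
    for name, required in _SUBTYPE_RULES.get(main_type, []):
        if all(m in elevated for m in required):
            return name
    return "T4"


@dataclass
class ClusterModel:
    """Fitted two-stage model: SOM/metacluster assignments and the gated
    metacluster -> type annotations at each stage."""

    grid_main: tuple[int, int]
    grid_sub: tuple[int, int]
    k_main: int
    k_sub: int
    main_annotation: dict[int, str] = field(default_factory=dict)
    sub_annotation: dict[tuple[str, int], str] = field(default_factory=dict)


def _metacluster(values: np.ndarray, grid, k, seed) -> np.ndarray:
    """SOM + Louvain-on-node-means; returns a metacluster label per cell."""
    nodes, _ = som_metacluster(values, grid=grid, seed=seed)
    occupied = np.unique(nodes)
    if len(occupied) < 2:
        return np.zeros(len(values), dtype=int)
    node_means = np.stack([values[nodes == nd].mean(axis=0) for nd in occupied])
    k_eff = min(k, len(occupied) - 1)
    node_labels = graph_cluster_nodes(node_means, k_neighbors=k_eff, seed=seed)
    lut = dict(zip(occupied, node_labels))
    return np.array([lut[nd] for nd in nodes], dtype=int)


def phenotype_cells(
    cells: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    grid_main: tuple[int, int] = (10, 10),
    grid_sub: tuple[int, int] = (10, 10),
    k_main: int = 5,
    k_sub: int = 5,
    elevated_threshold: float = ELEVATED_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, ClusterModel]:
    """Run the full two-stage pipeline and annotate every cell.

    Stage 1 clusters on lineage markers and gates metaclusters into
    lymphoid / myeloid / other; stage 2 re-clusters each group on all
    non-checkpoint markers and gates the 20 subtypes ('other' splits into
    stromal vs tumor here). Returns the annotated table (adds metacluster,
    main_type, subtype) and the fitted model.
    """
    missing = [m for m in panel.lineage_markers if m not in cells.columns]
    if missing:
        raise ValueError(f"cells table lacks required markers: {missing}")
    model = ClusterModel(grid_main, grid_sub, k_main, k_sub)
    out = cells.copy()

    x_main = preprocess(cells[list(panel.lineage_markers)])
    mc_main = _metacluster(x_main, grid_main, k_main, seed)
    main_type = np.empty(len(cells), dtype=object)
    for mc in np.unique(mc_main):
        sel = mc_main == mc
        elevated = {
            m for i, m in enumerate(panel.lineage_markers)
            if x_main[sel, i].mean() >= elevated_threshold
        }
        label = gate_main_type(elevated)
        model.main_annotation[int(mc)] = label
        main_type[sel] = label

    sub_markers = list(panel.subtyping_markers)
    subtype = np.empty(len(cells), dtype=object)
    metacluster = np.empty(len(cells), dtype=object)
    for group in ("lymphoid", "myeloid", "other"):
        sel = main_type == group
        n = int(sel.sum())
        if n == 0:
            continue
        if n < 10:  # too few cells to cluster: gate the pooled profile
            mc_sub = np.zeros(n, dtype=int)
            x_sub = preprocess(cells.loc[sel, sub_markers]) if n >= 2 else np.zeros(
                (n, len(sub_markers)))
        else:
            x_sub = preprocess(cells.loc[sel, sub_markers])
            mc_sub = _metacluster(x_sub, grid_sub, k_sub, seed + 1)
        names = np.empty(n, dtype=object)
        for mc in np.unique(mc_sub):
            msel = mc_sub == mc
            elevated = {
                m for i, m in enumerate(sub_markers)
                if x_sub[msel, i].mean() >= elevated_threshold
            }
            name = gate_subtype(elevated, group)
            model.sub_annotation[(group, int(mc))] = name
            names[msel] = name
        subtype[sel] = names
        metacluster[sel] = [f"{group}_{m}" for m in mc_sub]

    out["metacluster"] = metacluster
    out["subtype"] = subtype
    out["main_type"] = [SUBTYPE_ONTOLOGY[s] for s in subtype]
    return out, model


def compute_densities(cells: pd.DataFrame, label_col: str = "subtype") -> pd.DataFrame:
    """Per-image cell-type fractions (count of type / total cells per image).

    Rows (images) sum to 1 over the observed types."""
    if cells.empty:
        raise ValueError("cells table is empty")
    counts = cells.groupby(["image_id", label_col]).size().unstack(fill_value=0)
    dens = counts.div(counts.sum(axis=1), axis=0)
    dens.columns.name = None
    return dens
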