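"""Spatial community detection and cross-sample community typing.

Louvain modularity optimization on the 20 µm neighbor graph partitions each
image into highly interconnected multicellular subunits; their cell-type
composition vectors, min–max normalized per subtype across all communities,
are then clustered (kNN-Jaccard-Louvain, as in phenotyping) into recurring
community types shared across samples.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .phenotype import graph_cluster_nodes
from .spatial import NeighborGraph

__all__ = ["detect_communities", "community_composition", "type_communities",
           "archetype_community_profile"]


def detect_communities(
    graph: NeighborGraph,
    resolution: float = 0.5,
    min_size: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Louvain communities of the spatial graph; returns a label per cell.

    The default resolution 0.5 targets whole multicellular aggregates: at
    resolution 1.0 modularity optimization subdivides a single dense spatial
    cluster of a 20 µm geometric graph into arbitrary halves. Communities
    smaller than ``min_size`` are merged into the neighboring community they
    share the most edges with, or flagged unassigned (-1) when they touch no
    other community.
    """
    n = len(graph.xy)
    if n == 0:
        raise ValueError("empty graph")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, graph.edges))
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for li, members in enumerate(comms):
        labels[members] = li

    # merge undersized communities into their most-connected neighbor
    sizes = np.bincount(labels)
    for small in np.where(sizes < min_size)[0]:
        members = np.where(labels == small)[0]
        edge_votes: dict[int, int] = {}
        for m in members:
            for nb in g.neighbors(m):
                lb = labels[nb]
                if lb != small and lb != -1 and sizes[lb] >= min_size:
                    edge_votes[lb] = edge_votes.get(lb, 0) + 1
        if edge_votes:
            target = max(sorted(edge_votes), key=edge_votes.get)
            labels[members] = target
        else:
            labels[members] = -1
    # relabel contiguous from 0, unassigned stays -1
    kept = np.unique(labels[labels >= 0])
    lut = {old: new for new, old in enumerate(kept)}
    return np.array([lut.get(l, -1) for l in labels], dtype=int)


def community_composition(
    cells: pd.DataFrame, community_col: str = "community", label_col: str = "subtype"
) -> pd.DataFrame:
    """Per (image, community) size and subtype-fraction vector (rows sum to 1);
    unassigned cells (community -1) are dropped."""
    assigned = cells[cells[community_col] >= 0]
    counts = (
        assigned.groupby(["image_id", community_col, label_col]).size()
        .unstack(fill_value=0)
    )
    comp = counts.div(counts.sum(axis=1), axis=0)
    comp.insert(0, "size", counts.sum(axis=1))
    comp = comp.reset_index().rename(columns={community_col: "community_id"})
    comp.columns.name = None
    return comp


def type_communities(
    compositions: pd.DataFrame,
    k_neighbors: int = 30,
    seed: int = 0,
    meta_cols: tuple[str, ...] = ("image_id", "community_id", "size"),
) -> pd.DataFrame:
    """Cluster community composition vectors (pooled over images) into
    recurring community types.

    Each subtype fraction is min–max normalized across all communities, then
    the kNN-Jaccard-Louvain clustering used for phenotyping assigns a shared
    community_type label.
    """
    frac_cols = [c for c in compositions.columns if c not in meta_cols]
    x = compositions[frac_cols].to_numpy(dtype=float)
    if len(x) <= k_neighbors:
        raise ValueError(
            f"{len(x)} communities <= k_neighbors={k_neighbors}; use a smaller k"
        )
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    xn = (x - lo) / rng_
    labels = graph_cluster_nodes(xn, k_neighbors=k_neighbors, seed=seed)
    out = compositions.copy()
    out["community_type"] = labels
    return out


def archetype_community_profile(
    typed: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Archetype x community-type fraction matrix (rows sum to 1), weighting
    each community equally within its ROI's archetype."""
    merged = typed.merge(meta[["image_id", "archetype"]], on="image_id")
    counts = merged.groupby(["archetype", "community_type"]).size().unstack(fill_value=0)
    prof = counts.div(counts.sum(axis=1), axis=0)
    prof.columns.name = None
    return prof
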