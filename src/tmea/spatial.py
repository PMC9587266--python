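"""Spatial neighborhood analysis: interaction/avoidance permutation testing.

Cells within 20 µm (centroid-to-centroid, inclusive) are neighbors. For each
ordered cell-type pair (A, B) in an image, the observed neighboring-pair
count C_obs is compared with a null built by shuffling the type labels over
the fixed graph N_perm times:

    P_AB = 1                                         if C_obs = 0
    P_AB = (#{C_perm >= (<=) C_obs} + 1)/(N_perm+1)  otherwise

with >= for interaction and <= for avoidance. A pair is called at
alpha = 0.01. Cohort summaries report the fraction of images with a
significant call per pair; nearest-distance distributions quantify
proximity between two types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

__all__ = [
    "NeighborGraph",
    "build_graph",
    "permutation_test",
    "summarize_frequency",
    "regional_correlation",
    "nearest_distance",
]


@dataclass
class NeighborGraph:
    """Undirected neighbor graph of one image: cell centroids (µm) and the
    edge list of all pairs within ``threshold_um``."""

    image_id: str
    xy: np.ndarray  # (n, 2) µm
    edges: np.ndarray  # (m, 2) int indices, i < j
    threshold_um: float


def build_graph(cells: pd.DataFrame, threshold_um: float = 20.0,
                image_id: str = "") -> NeighborGraph:
    """All and only centroid pairs with Euclidean distance <= threshold
    (inclusive) become edges; no self-edges."""
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) == 0:
        raise ValueError("image has no cells")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(threshold_um, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))] if len(pairs) else pairs.reshape(0, 2)
    return NeighborGraph(image_id=image_id, xy=xy, edges=pairs, threshold_um=threshold_um)


def _pair_counts(codes_i: np.ndarray, codes_j: np.ndarray, k: int) -> np.ndarray:
    """Symmetric k x k matrix of undirected neighboring-pair counts."""
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (codes_i, codes_j), 1)
    counts = counts + counts.T
    # undirected A==A pairs were counted once per edge then doubled; halve back
    np.fill_diagonal(counts, np.diag(counts) // 2)
    return counts


def permutation_test(
    graph: NeighborGraph,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Permutation interaction/avoidance test for every ordered type pair.

    Labels are shuffled uniformly over nodes (graph fixed), preserving type
    counts. Returns one row per ordered pair with C_obs, p_interaction,
    p_avoidance and the call at ``alpha``; pairs where either type is absent
    from the image are skipped (call would be meaningless).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    if len(labels) != len(graph.xy):
        raise ValueError("labels length must match graph nodes")
    types, codes = np.unique(labels, return_inverse=True)
    if len(types) < 2:
        raise ValueError("need at least 2 distinct labels")
    k = len(types)
    ei, ej = (graph.edges[:, 0], graph.edges[:, 1]) if len(graph.edges) else (
        np.empty(0, dtype=int), np.empty(0, dtype=int))

    c_obs = _pair_counts(codes[ei], codes[ej], k)
    rng = np.random.default_rng(seed)
    n_ge = np.zeros((k, k), dtype=np.int64)
    n_le = np.zeros((k, k), dtype=np.int64)
    perm_codes = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        c_perm = _pair_counts(perm_codes[ei], perm_codes[ej], k)
        n_ge += c_perm >= c_obs
        n_le += c_perm <= c_obs
    p_int = (n_ge + 1) / (n_perm + 1)
    p_avd = (n_le + 1) / (n_perm + 1)
    zero = c_obs == 0
    p_int[zero] = 1.0
    p_avd[zero] = 1.0

    rows = []
    for a in range(k):
        for b in range(k):
            call = "ns"
            if c_obs[a, b] > 0 and p_int[a, b] <= alpha:
                call = "interaction"
            elif p_avd[a, b] <= alpha:
                call = "avoidance"
            rows.append(
                {
                    "image_id": graph.image_id,
                    "type_a": types[a],
                    "type_b": types[b],
                    "c_obs": int(c_obs[a, b]),
                    "p_interaction": float(p_int[a, b]),
                    "p_avoidance": float(p_avd[a, b]),
                    "call": call,
                }
            )
    return pd.DataFrame(rows)


def summarize_frequency(results: pd.DataFrame, images: list[str] | None = None) -> pd.DataFrame:
    """Fraction of images with a significant interaction (and avoidance) call
    per ordered type pair.

    ``images`` fixes the denominator (e.g. all images of a group); images
    without a row for a pair — the type was absent — count as ns.
    """
    if results.empty and not images:
        raise ValueError("no results to summarize")
    denom = len(images) if images is not None else results["image_id"].nunique()
    grp = results.groupby(["type_a", "type_b"])["call"]
    out = pd.DataFrame(
        {
            "frac_interaction": grp.apply(lambda c: (c == "interaction").sum() / denom),
            "frac_avoidance": grp.apply(lambda c: (c == "avoidance").sum() / denom),
        }
    ).reset_index()
    return out


def regional_correlation(densities: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of cell-type densities across images.

    Returns a symmetric type x type matrix with unit diagonal; types with
    constant density across images get NaN (undefined rank correlation).
    """
    if len(densities) < 3:
        raise ValueError("need densities from at least 3 images")
    import warnings

    from scipy.stats import ConstantInputWarning

    x = densities.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # constant columns are reported as NaN below, not an error
        warnings.simplefilter("ignore", ConstantInputWarning)
        rho = spearmanr(x)[0]
    if np.isscalar(rho):  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    const = x.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=densities.columns, columns=densities.columns)


def nearest_distance(
    cells: pd.DataFrame, source_type: str, target_type: str, label_col: str = "subtype"
) -> pd.DataFrame:
    """Per source cell, the shortest distance (µm) to any target-type cell in
    the same image.

    Source cells in images with no target cells are excluded and counted in
    the 'n_excluded' attribute (``DataFrame.attrs``).
    """
    src = cells[cells[label_col] == source_type]
    if src.empty:
        raise ValueError(f"no cells of source type {source_type!r}")
    rows = []
    n_excluded = 0
    for img, s in src.groupby("image_id"):
        tgt = cells[(cells["image_id"] == img) & (cells[label_col] == target_type)]
        if tgt.empty:
            n_excluded += len(s)
            continue
        tree = cKDTree(tgt[["x_um", "y_um"]].to_numpy(dtype=float))
        d, _ = tree.query(s[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
        # source == target: distance to self is 0; use the 2nd neighbor then
        if source_type == target_type and len(tgt) > 1:
            d, _ = tree.query(s[["x_um", "y_um"]].to_numpy(dtype=float), k=2)
            d = d[:, 1]
        for dist in np.atleast_1d(d):
            rows.append({"image_id": img, "distance_um": float(dist)})
    out = pd.DataFrame(rows, columns=["image_id", "distance_um"])
    out.attrs["n_excluded"] = n_excluded
    return out
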