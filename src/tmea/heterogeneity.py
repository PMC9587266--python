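"""Intrapatient heterogeneity via Shannon entropy of cell-type composition.

H_i = -sum_c P_c log2(P_c) over the cell-type frequencies P_c that occur in
sample i; to remove the dependence on cell number, each sample is subsampled
to a fixed size (default 1000 cells, 3 replicates) and the replicate
entropies are averaged. Group contrasts (core tumor vs invasive margin,
responder vs nonresponder) use the two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg correction across the family of comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["shannon_entropy", "subsampled_entropy", "compare_entropy"]


def shannon_entropy(fractions) -> float:
    """Shannon entropy in bits of a composition vector; zero entries are
    skipped (only occurring types contribute)."""
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def subsampled_entropy(
    labels,
    n: int = 1000,
    reps: int = 3,
    seed: int = 0,
) -> dict:
    """Mean Shannon entropy over ``reps`` subsamples of ``n`` cells (without
    replacement) from one sample's cell-type labels.

    Samples smaller than ``n`` use all cells (replicates then coincide).
    Returns a dict with per-replicate entropies, their mean, and the number
    of cells drawn per replicate.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("sample has no cells")
    rng = np.random.default_rng(seed)
    n_use = min(n, len(labels))
    ent = []
    for _ in range(reps):
        draw = rng.choice(labels, size=n_use, replace=False)
        _, counts = np.unique(draw, return_counts=True)
        ent.append(shannon_entropy(counts / counts.sum()))
    return {"H_reps": ent, "H_mean": float(np.mean(ent)), "n_cells_used": int(n_use)}


def entropy_by_sample(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    label_col: str = "subtype",
    n: int = 1000,
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsampled entropy for every (patient, region) sample, pooling the
    cells of that patient-region's images."""
    merged = cells.merge(meta[["image_id", "patient", "region", "response"]], on="image_id")
    rows = []
    for i, ((pat, reg), grp) in enumerate(merged.groupby(["patient", "region"])):
        res = subsampled_entropy(grp[label_col].to_numpy(), n=n, reps=reps, seed=seed + i)
        rows.append(
            {
                "patient": pat,
                "region": reg,
                "response": grp["response"].iloc[0],
                "H_mean": res["H_mean"],
                "n_cells_used": res["n_cells_used"],
            }
        )
    return pd.DataFrame(rows)


def compare_entropy(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between every named pair of entropy
    groups, BH-adjusted across the family.

    ``groups`` maps contrast name -> (values_a, values_b) pairs.
    """
    rows = []
    for name, (a, b) in groups.items():
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group in contrast {name!r}")
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if no_ties and len(pooled) <= 40 else "asymptotic"
        stat, p = mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"contrast": name, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
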