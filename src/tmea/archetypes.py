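"""TME-archetype discovery and hot/cold patient stratification.

Cell types differentially abundant between responders and nonresponders
(|log2FC| >= 1.2, BH-adjusted Wilcoxon p <= 0.05, overall density >= 1%) are
selected; invasive-margin ROIs are then clustered on the z-scaled selected
densities (Euclidean distance, complete linkage, cut at k = 6) into six
archetypes, categorized immune-hot or immune-cold from their composition.
Patients are called hot/cold by majority vote over their IM ROIs (ties ->
hot). Downstream summaries: ROI/patient classification arithmetic, exact
binomial TLS-enrichment CIs, and age-adjusted Cox models per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "differential_abundance",
    "ArchetypeModel",
    "cluster_archetypes",
    "assign_hot_cold",
    "vote_patients",
    "classification_metrics",
    "tls_enrichment",
    "cox_by_celltype",
]

#: Hot-defining cell types: enrichment of any of these marks an archetype hot.
HOT_CELL_TYPES = ("B", "CD4+T", "CD8+T", "MC4")

#: Archetype naming rule: dominant z-scaled cell type -> prototype name.
_DOMINANT_NAME = {"B": "H1", "CD4+T": "H1", "CD8+T": "H3", "MC4": "H2",
                  "T1": "C1", "MC2": "C2"}


def differential_abundance(
    densities: pd.DataFrame,
    response: pd.Series,
    fc_min: float = 1.2,
    alpha: float = 0.05,
    density_min: float = 0.01,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Responder-vs-nonresponder differential cell-type abundance.

    ``densities``: image x cell-type fractions; ``response``: R/NR per image
    (aligned on index). log2FC = log2((mean_R + eps)/(mean_NR + eps));
    two-sided Wilcoxon per type, BH across types. A type passes selection iff
    |log2FC| >= fc_min, adjusted p <= alpha and overall mean density >=
    density_min.
    """
    response = response.loc[densities.index]
    is_r = (response == "R").to_numpy()
    if is_r.all() or (~is_r).all():
        raise ValueError("both R and NR images are required")
    rows = []
    for ct in densities.columns:
        v = densities[ct].to_numpy(dtype=float)
        mean_r, mean_nr = v[is_r].mean(), v[~is_r].mean()
        log2fc = float(np.log2((mean_r + eps) / (mean_nr + eps)))
        _, p = mannwhitneyu(v[is_r], v[~is_r], alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "mean_R": mean_r,
                "mean_NR": mean_nr,
                "overall_density": v.mean(),
                "log2fc": log2fc,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["passes_selection"] = (
        (out["log2fc"].abs() >= fc_min)
        & (out["p_adj"] <= alpha)
        & (out["overall_density"] >= density_min)
    )
    return out


@dataclass
class ArchetypeModel:
    """Fitted archetype clustering: selection, scaling, linkage and labels."""

    selected_types: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    linkage: np.ndarray
    k: int
    roi_labels: pd.Series  # image_id -> archetype name
    z_profiles: pd.DataFrame  # archetype x selected type mean z-score
    category: dict[str, str] = field(default_factory=dict)  # archetype -> hot/cold


def cluster_archetypes(
    densities: pd.DataFrame, selected_types: list[str], k: int = 6
) -> ArchetypeModel:
    """Hierarchically cluster ROIs on z-scaled selected cell-type densities
    (Euclidean, complete linkage, cut at ``k``).

    Archetype names come from each cluster's dominant z-scaled type via the
    field convention (B/CD4+T -> H1-like, MC4 -> H2, CD8+T -> H3, CAIX+ tumor
    -> C1, MC2 -> C2, none elevated -> C3); collisions get suffixes.
    """
    if len(densities) < k:
        raise ValueError(f"need >= k={k} ROIs, got {len(densities)}")
    x = densities[selected_types].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe
    link = hierarchy.linkage(z, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")

    # name clusters by dominant mean z-profile
    names: dict[int, str] = {}
    profiles = {}
    used: dict[str, int] = {}
    for cl in sorted(np.unique(labels)):
        prof = z[labels == cl].mean(axis=0)
        profiles[cl] = prof
        if prof.max() > 0:
            dom = selected_types[int(prof.argmax())]
            base = _DOMINANT_NAME.get(dom, "C3")
        else:
            base = "C3"
        used[base] = used.get(base, 0) + 1
        names[cl] = base if used[base] == 1 else f"{base}.{used[base]}"
    roi_labels = pd.Series([names[l] for l in labels], index=densities.index,
                           name="archetype")
    z_prof = pd.DataFrame(
        {names[cl]: profiles[cl] for cl in sorted(profiles)}, index=selected_types
    ).T
    model = ArchetypeModel(
        selected_types=list(selected_types), scale_mean=mu, scale_sd=sd_safe,
        linkage=link, k=k, roi_labels=roi_labels, z_profiles=z_prof,
    )
    model.category = assign_hot_cold(model)
    return model


def assign_hot_cold(
    model: ArchetypeModel, override: dict[str, str] | None = None
) -> dict[str, str]:
    """Categorize each archetype: hot iff its mean z-scaled abundance of any
    hot-defining type (B, CD4+T, CD8+T, MC4) is positive; else cold.

    ``override`` maps archetype -> category and wins where present.
    """
    cats = {}
    hot_cols = [t for t in HOT_CELL_TYPES if t in model.z_profiles.columns]
    for arch, prof in model.z_profiles.iterrows():
        hot = any(prof[t] > 0 for t in hot_cols)
        cats[arch] = "hot" if hot else "cold"
    if override:
        cats.update(override)
    return cats


def vote_patients(meta: pd.DataFrame, category: dict[str, str]) -> pd.DataFrame:
    """Majority-vote hot/cold per patient over IM-ROI archetype categories;
    exact ties are called hot (flagged). Patients with no IM ROI are dropped.

    ``meta`` needs image_id, patient, region and archetype columns.
    """
    im = meta[meta["region"] == "IM"].copy()
    im["cat"] = im["archetype"].map(category)
    rows = []
    for pat, grp in im.groupby("patient"):
        n_hot = int((grp["cat"] == "hot").sum())
        n_cold = int((grp["cat"] == "cold").sum())
        tie = n_hot == n_cold
        rows.append(
            {
                "patient": pat,
                "n_hot_rois": n_hot,
                "n_cold_rois": n_cold,
                "voted_category": "hot" if n_hot >= n_cold else "cold",
                "ties_resolved_hot": tie,
            }
        )
    return pd.DataFrame(rows)


def classification_metrics(
    roi_category: pd.Series,
    roi_response: pd.Series,
    patient_category: pd.Series | None = None,
    patient_response: pd.Series | None = None,
) -> dict:
    """ROI-level accuracy and patient-level objective response rates.

    ROI level: percent of responder ROIs called hot, percent of nonresponder
    ROIs called cold. Patient level (if given): ORR (% responders) within the
    hot and within the cold patient group.
    """
    roi_response = roi_response.loc[roi_category.index]
    is_r = roi_response == "R"
    out = {
        "responder_rois": int(is_r.sum()),
        "responder_rois_hot": int((is_r & (roi_category == "hot")).sum()),
        "nonresponder_rois": int((~is_r).sum()),
        "nonresponder_rois_cold": int((~is_r & (roi_category == "cold")).sum()),
    }
    out["responder_roi_accuracy_pct"] = (
        100.0 * out["responder_rois_hot"] / out["responder_rois"]
        if out["responder_rois"] else float("nan")
    )
    out["nonresponder_roi_accuracy_pct"] = (
        100.0 * out["nonresponder_rois_cold"] / out["nonresponder_rois"]
        if out["nonresponder_rois"] else float("nan")
    )
    if patient_category is not None:
        patient_response = patient_response.loc[patient_category.index]
        for cat in ("hot", "cold"):
            sel = patient_category == cat
            n = int(sel.sum())
            resp = int((sel & (patient_response == "R")).sum())
            out[f"n_{cat}_patients"] = n
            out[f"n_{cat}_responders"] = resp
            out[f"orr_{cat}_pct"] = 100.0 * resp / n if n else float("nan")
    return out


def tls_enrichment(meta: pd.DataFrame, archetype_col: str = "archetype") -> pd.DataFrame:
    """Among TLS-positive ROIs, the fraction per archetype with an exact
    Clopper–Pearson 95% CI."""
    tls = meta[meta["tls"].astype(bool)]
    if tls.empty:
        return pd.DataFrame(columns=["archetype", "successes", "trials",
                                     "fraction", "ci_lower", "ci_upper"])
    n = len(tls)
    rows = []
    for arch, grp in tls.groupby(archetype_col):
        x = len(grp)
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        rows.append(
            {
                "archetype": arch,
                "successes": x,
                "trials": n,
                "fraction": x / n,
                "ci_lower": float(lo),
                "ci_upper": float(hi),
            }
        )
    return pd.DataFrame(rows)


def cox_by_celltype(
    densities: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Univariate Cox proportional-hazards per cell type, adjusted for age.

    ``densities``: patient x cell-type table; ``survival``: patient, time,
    event, age. Returns HR per unit density with Wald 95% CI; non-converging
    or degenerate fits are flagged rather than fatal.
    """
    from lifelines import CoxPHFitter

    surv = survival.set_index("patient").loc[densities.index]
    if int(surv["event"].sum()) < 1 or len(surv) < 10:
        raise ValueError("need >= 10 patients with at least one event")
    rows = []
    for ct in densities.columns:
        rec = {"cell_type": ct, "hr": np.nan, "ci_lower": np.nan,
               "ci_upper": np.nan, "p": np.nan, "flag": ""}
        v = densities[ct].to_numpy(dtype=float)
        if v.std() == 0:
            rec["flag"] = "constant density"
            rows.append(rec)
            continue
        df = pd.DataFrame(
            {"density": v, "age": surv["age"].to_numpy(),
             "time": surv["time"].to_numpy(), "event": surv["event"].to_numpy()}
        )
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            rec["hr"] = float(np.exp(cph.params_["density"]))
            ci = cph.confidence_intervals_
            rec["ci_lower"] = float(np.exp(ci.loc["density"].iloc[0]))
            rec["ci_upper"] = float(np.exp(ci.loc["density"].iloc[1]))
            rec["p"] = float(cph.summary.loc["density", "p"])
        except Exception as e:  # noqa: BLE001 - convergence failures flagged
            rec["flag"] = f"fit failed: {e}"
        rows.append(rec)
    return pd.DataFrame(rows)
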