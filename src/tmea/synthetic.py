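"""Synthetic IMC cohort generator with planted, recoverable structure.

Generates everything the downstream pipeline consumes — multichannel images
with label masks, per-cell marker-intensity tables, ROI metadata, a bulk
expression matrix and survival data — from a single seeded configuration, so
that every analysis stage can be validated against known ground truth.

The planted structure mirrors a melanoma anti-PD-1 cohort: 20 cell subtypes
with marker-specific mean profiles, cells placed in spatial clusters
("community motifs"), per-ROI subtype compositions drawn from six
tumor-microenvironment archetypes (three immune-hot, three immune-cold),
responder/nonresponder labels tied to the hot/cold category, Weibull survival
with a hot-vs-cold hazard ratio, and a bulk log2 expression matrix in which a
fixed up/down gene signature separates hot from cold patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, MarkerPanel, SUBTYPES, SUBTYPE_ONTOLOGY

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "SurvivalParams",
    "default_celltype_profiles",
    "default_archetype_compositions",
    "generate_cell_positions",
    "render_image",
    "generate_bulk_expression",
    "generate_survival",
    "generate_cohort",
    "write_cohort",
]

#: Intensity (counts/pixel) of a subtype's defining markers vs all others;
#: non-expressed markers sit well below the background rate so that decoy
#: based positive-calling is meaningful on synthetic images.
_HIGH = 10.0
_LOW = 0.02

#: Defining (elevated) markers per subtype; all other markers sit at _LOW.
_SUBTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "CD4+T": ("CD45", "CD3", "CD4"),
    "CD8+T": ("CD45", "CD3", "CD8a"),
    "DPT": ("CD45", "CD3", "CD4", "CD8a"),
    "Treg": ("CD45", "CD3", "CD4", "FoxP3"),
    "B": ("CD45", "CD20", "CD19"),
    "MC1": ("CD45", "CD14", "CD11b", "IDO"),
    "MC2": ("CD45", "CD14", "CD11b", "VEGF"),
    "MC3": ("CD45", "CD14", "CD11b", "CAIX"),
    "MC4": ("CD45", "CD14", "HLA-DR", "CD11c"),
    "MC5": ("CD45", "CD14", "CD16", "HLA-DR"),
    "MC6": ("CD45", "CD14", "HLA-DR", "CD68"),
    "S1": ("CollagenI",),
    "S2": ("FAP",),
    "S3": ("PDGFRb",),
    "S4": ("aSMA",),
    "S5": ("Vimentin",),
    "T1": ("CAIX", "E-cadherin"),
    "T2": ("Ki67", "E-cadherin"),
    "T3": ("VEGF", "E-cadherin"),
    "T4": (),  # non-classified: no elevated marker
}

_HOT_ARCHETYPES = ("H1", "H2", "H3")
_COLD_ARCHETYPES = ("C1", "C2", "C3")

#: Fractions of the six response-discriminating subtypes per archetype; the
#: remaining 13 subtypes sit at 0.02 each and T4 absorbs the remainder, so
#: only these six differ between hot and cold ROIs.
_ARCHETYPE_SIGNATURE_FRACTIONS: dict[str, dict[str, float]] = {
    "H1": {"B": 0.20, "CD4+T": 0.20, "CD8+T": 0.10, "MC4": 0.02, "MC2": 0.02, "T1": 0.03},
    "H2": {"B": 0.02, "CD4+T": 0.05, "CD8+T": 0.05, "MC4": 0.30, "MC2": 0.02, "T1": 0.05},
    "H3": {"B": 0.02, "CD4+T": 0.05, "CD8+T": 0.28, "MC4": 0.08, "MC2": 0.02, "T1": 0.05},
    "C1": {"B": 0.01, "CD4+T": 0.02, "CD8+T": 0.02, "MC4": 0.01, "MC2": 0.08, "T1": 0.38},
    "C2": {"B": 0.01, "CD4+T": 0.02, "CD8+T": 0.02, "MC4": 0.02, "MC2": 0.28, "T1": 0.10},
    "C3": {"B": 0.02, "CD4+T": 0.03, "CD8+T": 0.03, "MC4": 0.02, "MC2": 0.04, "T1": 0.08},
}

#: Probability that an IM ROI of each archetype contains a tertiary lymphoid
#: structure (lymphocyte aggregate); absent from cold archetypes.
_TLS_PROBABILITY = {"H1": 0.45, "H3": 0.10}


def default_celltype_profiles(panel: MarkerPanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Mean marker intensity (counts/pixel) per subtype: defining markers high,
    all others low. Rows: 20 subtypes; columns: panel markers."""
    prof = pd.DataFrame(_LOW, index=list(SUBTYPES), columns=list(panel.names), dtype=float)
    for subtype, markers in _SUBTYPE_MARKERS.items():
        for m in markers:
            prof.loc[subtype, m] = _HIGH
    return prof


def default_archetype_compositions() -> pd.DataFrame:
    """Expected subtype-fraction vector per archetype (rows sum to 1)."""
    sig_types = set().union(*(d.keys() for d in _ARCHETYPE_SIGNATURE_FRACTIONS.values()))
    other = [s for s in SUBTYPES if s not in sig_types and s != "T4"]
    rows = {}
    for arch, sig in _ARCHETYPE_SIGNATURE_FRACTIONS.items():
        vec = pd.Series(0.0, index=list(SUBTYPES))
        for s, f in sig.items():
            vec[s] = f
        vec[other] = 0.02
        vec["T4"] = 1.0 - vec.sum()
        rows[arch] = vec
    comp = pd.DataFrame(rows).T
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)
    return comp


@dataclass(frozen=True)
class SurvivalParams:
    """Weibull survival model per hot/cold patient group.

    Median survival = scale * ln(2)^(1/shape); the default scales give a
    cold-vs-hot hazard ratio of about 3 at shape 1 (exponential).
    """

    scale_hot: float = 60.0  # months
    scale_cold: float = 20.0
    shape: float = 1.0
    censor_scale: float = 120.0  # exponential censoring-time scale (months)
    age_mean: float = 60.0
    age_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_hot <= 0 or self.scale_cold <= 0 or self.shape <= 0:
            raise ValueError("hazard (scale/shape) parameters must be positive")


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    Cells are placed by a cluster process: motif centers uniform over the
    image, members scattered isotropically (``cluster_sigma_um``) around the
    center, with a minimum center-to-center spacing of 4 µm. Per-cell marker
    means are Poisson-sampled at ``profile + background_noise`` counts/pixel
    over the cell footprint.
    """

    n_patients: int = 20
    rois_per_patient_ct: int = 2
    rois_per_patient_im: int = 2
    image_size_um: tuple[float, float] = (400.0, 400.0)
    n_markers: int = 35
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)
    celltype_profiles: pd.DataFrame | None = None  # subtypes x markers
    community_motifs: list[np.ndarray] | None = None  # composition vectors
    archetype_compositions: pd.DataFrame | None = None  # archetype x subtype
    background_noise: float = 0.1  # Poisson rate per pixel per channel
    responder_fraction: float = 0.5
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    cells_per_roi: int = 1000
    cells_per_cluster: int = 80
    cluster_sigma_um: float = 15.0
    min_spacing_um: float = 4.0
    cell_radius_um: float = 5.0
    pixel_size_um: float = 1.0  # Hyperion ablation raster
    seed: int = 0

    def __post_init__(self) -> None:
        if self.celltype_profiles is None:
            self.celltype_profiles = default_celltype_profiles(self.panel)
        if self.archetype_compositions is None:
            self.archetype_compositions = default_archetype_compositions()
        if (self.celltype_profiles.values < 0).any():
            raise ValueError("celltype profile intensities must be >= 0")
        if self.background_noise < 0:
            raise ValueError("background_noise must be >= 0")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.community_motifs is not None:
            for v in self.community_motifs:
                if abs(float(np.sum(v)) - 1.0) > 1e-9:
                    raise ValueError("every motif composition must sum to 1")
        comp = self.archetype_compositions
        if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("archetype compositions must sum to 1")

    @property
    def subtypes(self) -> list[str]:
        return list(self.celltype_profiles.index)


@dataclass
class SyntheticCohort:
    """A generated cohort: per-cell table, per-ROI metadata, bulk expression,
    survival, and (optionally) rendered channel stacks + label masks."""

    cells: pd.DataFrame  # cell_id, image_id, x_um, y_um, area, markers..., true_subtype
    meta: pd.DataFrame  # image_id, patient, region, response, tls, archetype, category
    bulk_expr: pd.DataFrame  # genes x samples, log2 scale
    survival: pd.DataFrame  # patient, time, event, age
    images: dict[str, np.ndarray] = field(default_factory=dict)  # C x H x W
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # H x W int


# ---------------------------------------------------------------------------
# spatial placement


class _SpacingGrid:
    """Uniform hash grid for O(1) minimum-spacing rejection checks."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(self, x: float, y: float) -> bool:
        s = self.spacing
        gx, gy = int(x // s), int(y // s)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in self.cells.get((gx + dx, gy + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < s * s:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        s = self.spacing
        self.cells.setdefault((int(x // s), int(y // s)), []).append((x, y))


def generate_cell_positions(
    config: CohortConfig,
    image_index: int,
    motifs: list[np.ndarray] | None = None,
    n_cells: int | None = None,
    centers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Place cells for one image by a clustered point process.

    Motif centers are uniform over the image (or given explicitly via
    ``centers``); members are isotropic Gaussian (sigma =
    ``cluster_sigma_um``) around their center, clipped to the image, with min
    spacing ``min_spacing_um`` enforced by rejection. Each cluster draws its
    subtype composition from one motif vector (probabilities over
    ``config.subtypes``), so planted motifs are recoverable as spatial
    communities.

    Returns a DataFrame with columns x_um, y_um, subtype, cluster_id.
    """
    if motifs is None:
        motifs = config.community_motifs
    if not motifs:
        raise ValueError("at least one community motif is required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101, image_index]))
    w, h = config.image_size_um
    n_cells = config.cells_per_roi if n_cells is None else n_cells
    if centers is not None:
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        n_clusters = len(centers)
    else:
        n_clusters = max(1, int(round(n_cells / config.cells_per_cluster)))

    grid = _SpacingGrid(config.min_spacing_um)
    rows: list[tuple[float, float, str, int]] = []
    subtypes = np.asarray(config.subtypes, dtype=object)
    sizes = np.full(n_clusters, n_cells // n_clusters)
    sizes[: n_cells % n_clusters] += 1
    for ci in range(n_clusters):
        center = centers[ci] if centers is not None else rng.uniform([0, 0], [w, h])
        motif = np.asarray(motifs[rng.integers(len(motifs))], dtype=float)
        placed = 0
        attempts = 0
        while placed < sizes[ci] and attempts < 200 * sizes[ci]:
            attempts += 1
            x, y = center + rng.normal(0.0, config.cluster_sigma_um, size=2)
            x = float(np.clip(x, 0, w - 1e-9))
            y = float(np.clip(y, 0, h - 1e-9))
            # zero-variance limit: all members sit at the center, spacing moot
            if config.cluster_sigma_um > 0:
                if not grid.ok(x, y):
                    continue
                grid.add(x, y)
            subtype = rng.choice(subtypes, p=motif)
            rows.append((x, y, str(subtype), ci))
            placed += 1
    return pd.DataFrame(rows, columns=["x_um", "y_um", "subtype", "cluster_id"])


# ---------------------------------------------------------------------------
# rendering


def render_image(
    cells: pd.DataFrame, config: CohortConfig, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render placed cells into a (channels, H, W) Poisson-count stack and a
    0-background integer label mask.

    Each cell is a disk of ``cell_radius_um``; disk overlaps are resolved by
    assigning contested pixels to the nearer center. Pixel counts are
    Poisson at rate profile + background inside cells, background alone
    outside; the additive background makes decoy-based subtraction unbiased.
    Mask label i+1 corresponds to row i of ``cells``.
    """
    unknown = set(cells["subtype"]) - set(config.celltype_profiles.index)
    if unknown:
        raise ValueError(f"no marker profile for subtypes: {sorted(unknown)}")
    px = config.pixel_size_um
    w_px = int(round(config.image_size_um[0] / px))
    h_px = int(round(config.image_size_um[1] / px))
    n_ch = len(config.panel.names)
    rng = np.random.default_rng(seed)

    mask = np.zeros((h_px, w_px), dtype=np.uint16)
    best_d2 = np.full((h_px, w_px), np.inf)
    r_px = config.cell_radius_um / px
    for i, (x, y) in enumerate(zip(cells["x_um"], cells["y_um"])):
        cx, cy = x / px, y / px
        x0, x1 = max(0, int(cx - r_px) - 1), min(w_px, int(cx + r_px) + 2)
        y0, y1 = max(0, int(cy - r_px) - 1), min(h_px, int(cy + r_px) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
        win = (d2 <= r_px**2) & (d2 < best_d2[y0:y1, x0:x1])
        sub_m = mask[y0:y1, x0:x1]
        sub_d = best_d2[y0:y1, x0:x1]
        sub_m[win] = i + 1
        sub_d[win] = d2[win]

    # per-label Poisson rate lookup (row 0 = background)
    rates = np.full((len(cells) + 1, n_ch), config.background_noise)
    if len(cells):
        rates[1:] += config.celltype_profiles.loc[cells["subtype"]].to_numpy()
    rate_stack = rates[mask.ravel()].T.reshape(n_ch, h_px, w_px)
    stack = rng.poisson(rate_stack).astype(np.float32)
    return stack, mask


# ---------------------------------------------------------------------------
# cell-level intensity tables (image-free fast path)


def _sample_cell_means(
    subtypes: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell marker means as Poisson(area * (profile + bg)) / area — the
    distribution of a disk-mean under the rendering model, without rendering."""
    area_px = max(1, int(round(np.pi * (config.cell_radius_um / config.pixel_size_um) ** 2)))
    rates = config.celltype_profiles.loc[subtypes].to_numpy() + config.background_noise
    return rng.poisson(rates * area_px) / area_px


# ---------------------------------------------------------------------------
# bulk expression + survival


def generate_bulk_expression(
    patients: pd.DataFrame,
    up_genes: list[str],
    down_genes: list[str],
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_filler_genes: int = 120,
) -> pd.DataFrame:
    """Genes x samples log2 expression with the signature planted on hot
    patients: up_genes shifted +effect, down_genes −effect, plus Gaussian
    noise and >= 100 null filler genes.

    ``patients`` needs columns 'patient' and 'category' in {hot, cold}.
    """
    if set(up_genes) & set(down_genes):
        raise ValueError("up_genes and down_genes overlap")
    if n_filler_genes < 100:
        raise ValueError("need at least 100 filler genes")
    pats = patients.drop_duplicates("patient")
    rng = np.random.default_rng(seed)
    genes = list(up_genes) + list(down_genes) + [f"NULL{i:04d}" for i in range(n_filler_genes)]
    baseline = rng.uniform(3.0, 8.0, size=len(genes))
    hot = (pats["category"].to_numpy() == "hot").astype(float)
    shift = np.zeros(len(genes))
    shift[: len(up_genes)] = effect_log2fc
    shift[len(up_genes) : len(up_genes) + len(down_genes)] = -effect_log2fc
    expr = baseline[:, None] + shift[:, None] * hot[None, :]
    expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    return pd.DataFrame(expr, index=genes, columns=pats["patient"].tolist())


def generate_survival(
    patients: pd.DataFrame, params: SurvivalParams, seed: int = 0
) -> pd.DataFrame:
    """Weibull survival times per patient with group-specific scale (hot vs
    cold) and independent exponential censoring; returns patient, time,
    event, age."""
    if params.scale_hot <= 0 or params.scale_cold <= 0:
        raise ValueError("hazard scales must be positive")
    pats = patients.drop_duplicates("patient").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    scale = np.where(pats["category"] == "hot", params.scale_hot, params.scale_cold)
    t = scale * rng.weibull(params.shape, size=len(pats))
    c = rng.exponential(params.censor_scale, size=len(pats))
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    age = rng.normal(params.age_mean, params.age_sd, size=len(pats))
    return pd.DataFrame(
        {"patient": pats["patient"], "time": time, "event": event, "age": np.round(age, 1)}
    )


# ---------------------------------------------------------------------------
# cohort orchestration


def generate_cohort(
    config: CohortConfig | None = None,
    render: bool = False,
    signature_up: list[str] | None = None,
    signature_down: list[str] | None = None,
) -> SyntheticCohort:
    """Generate a full cohort under ``config`` (deterministic given its seed).

    Responders are assigned hot archetypes and nonresponders cold ones; all
    ROIs of a patient share the patient's archetype composition, used as the
    single community motif for that image. With ``render=True`` the channel
    stacks and label masks are rendered and per-cell means are extracted from
    pixels; otherwise cell means are Poisson-sampled directly at the disk
    footprint (identical distribution, no images).
    """
    from .signature import DEFAULT_SIGNATURE  # deferred: avoid cycle at import

    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    comp = config.archetype_compositions
    hot_arch = [a for a in comp.index if a in _HOT_ARCHETYPES]
    cold_arch = [a for a in comp.index if a in _COLD_ARCHETYPES]

    n_resp = int(round(config.responder_fraction * config.n_patients))
    meta_rows = []
    cell_frames = []
    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    image_index = 0
    for p in range(config.n_patients):
        patient = f"P{p:02d}"
        response = "R" if p < n_resp else "NR"
        pool = hot_arch if response == "R" else cold_arch
        archetype = pool[rng.integers(len(pool))]
        category = "hot" if archetype in _HOT_ARCHETYPES else "cold"
        motif = comp.loc[archetype].to_numpy()
        regions = ["CT"] * config.rois_per_patient_ct + ["IM"] * config.rois_per_patient_im
        for region in regions:
            image_id = f"{patient}_{region}_{image_index:03d}"
            pos = generate_cell_positions(config, image_index, motifs=[motif])
            tls = bool(
                region == "IM" and rng.random() < _TLS_PROBABILITY.get(archetype, 0.0)
            )
            if render:
                stack, mask = render_image(pos, config, seed=int(rng.integers(2**31)))
                images[image_id] = stack
                masks[image_id] = mask
                from .quantify import extract_cell_means

                tab = extract_cell_means(stack, mask, config.panel.names,
                                         pixel_size_um=config.pixel_size_um)
                tab = tab.drop(columns=["x_um", "y_um"]).join(
                    pos[["x_um", "y_um"]].reset_index(drop=True)
                )
            else:
                means = _sample_cell_means(pos["subtype"], config,
                                           np.random.default_rng(
                                               np.random.SeedSequence(
                                                   [config.seed, 211, image_index])))
                area = int(round(np.pi * (config.cell_radius_um / config.pixel_size_um) ** 2))
                tab = pd.DataFrame(means, columns=list(config.panel.names))
                tab.insert(0, "area", area)
                tab = pd.concat([pos[["x_um", "y_um"]].reset_index(drop=True), tab], axis=1)
                tab.insert(0, "cell_id", np.arange(1, len(tab) + 1))
            tab["image_id"] = image_id
            tab["true_subtype"] = pos["subtype"].to_numpy()
            tab["true_cluster"] = pos["cluster_id"].to_numpy()
            cell_frames.append(tab)
            meta_rows.append(
                {
                    "image_id": image_id,
                    "patient": patient,
                    "region": region,
                    "response": response,
                    "tls": tls,
                    "archetype": archetype,
                    "category": category,
                }
            )
            image_index += 1

    cells = pd.concat(cell_frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    patients = meta[["patient", "category"]].drop_duplicates("patient")
    up = signature_up if signature_up is not None else list(DEFAULT_SIGNATURE.up_genes)
    down = signature_down if signature_down is not None else list(DEFAULT_SIGNATURE.down_genes)
    bulk = generate_bulk_expression(
        patients, up, down, seed=int(np.random.default_rng(
            np.random.SeedSequence([config.seed, 307])).integers(2**31))
    )
    surv = generate_survival(
        patients, config.survival_params,
        seed=int(np.random.default_rng(
            np.random.SeedSequence([config.seed, 401])).integers(2**31)),
    )
    return SyntheticCohort(cells=cells, meta=meta, bulk_expr=bulk, survival=surv,
                           images=images, masks=masks)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write cells/meta/bulk/survival CSVs and, if rendered, per-ROI
    multi-page TIFF stacks (channel order = panel order) and 16-bit masks."""
    import pathlib

    import tifffile

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.cells.to_csv(out / "cells.csv", index=False)
    cohort.meta.to_csv(out / "meta.csv", index=False)
    cohort.bulk_expr.to_csv(out / "bulk_expr.csv")
    cohort.survival.to_csv(out / "survival.csv", index=False)
    for image_id, stack in cohort.images.items():
        tifffile.imwrite(out / f"{image_id}.tiff", stack)
        tifffile.imwrite(out / f"{image_id}_mask.tiff",
                         cohort.masks[image_id].astype(np.uint16))
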