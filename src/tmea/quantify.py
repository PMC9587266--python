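"""Single-cell quantification from channel stacks and label masks.

Pipeline: per-cell mean extraction → decoy-cell background estimation →
subtraction → empirical FDR positive-cell calling → cross-ROI normalization
on positive-cell medians. Decoy cells are pseudo-cells placed in cell-free
background; their per-channel means serve as the noise null both for
subtraction and for calling which cells genuinely express a marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DecoySet",
    "extract_cell_means",
    "generate_decoys",
    "subtract_background",
    "call_positive_cells",
    "normalize_across_rois",
    "read_stack",
]


@dataclass
class DecoySet:
    """Background pseudo-cells for one image: per-decoy channel means and
    the disk geometry they were measured on."""

    image_id: str
    means: np.ndarray  # (n_decoys, n_channels)
    centers: np.ndarray  # (n_decoys, 2) px (x, y)
    radius_um: float


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (channels, H, W) float array."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def extract_cell_means(
    stack: np.ndarray,
    mask: np.ndarray,
    channel_names,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Per-label mean intensity per channel plus unweighted pixel centroid.

    Returns one row per positive label in ``mask`` (ascending label order)
    with columns cell_id, x_um, y_um, area, then one column per channel.
    An empty mask yields an empty table.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.shape[1:] != mask.shape:
        raise ValueError(f"stack {stack.shape[1:]} and mask {mask.shape} disagree")
    if len(channel_names) != stack.shape[0]:
        raise ValueError("channel_names length must match stack channels")
    cols = ["cell_id", "x_um", "y_um", "area", *channel_names]
    if not mask.any():
        return pd.DataFrame(columns=cols)
    props = measure.regionprops_table(
        mask.astype(np.int64),
        intensity_image=np.moveaxis(stack, 0, -1),
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    df = pd.DataFrame(props)
    out = pd.DataFrame(
        {
            "cell_id": df["label"].astype(int),
            # centroid-0 is the row (y) coordinate; pixel centers at +0.5 px
            "x_um": (df["centroid-1"] + 0.5) * pixel_size_um,
            "y_um": (df["centroid-0"] + 0.5) * pixel_size_um,
            "area": df["area"].astype(int),
        }
    )
    for ci, name in enumerate(channel_names):
        out[name] = df[f"intensity_mean-{ci}"].to_numpy()
    return out.sort_values("cell_id", ignore_index=True)


def generate_decoys(
    stack: np.ndarray,
    mask: np.ndarray,
    n_decoys: int = 500,
    radius_um: float = 5.0,
    seed: int = 0,
    pixel_size_um: float = 1.0,
    clearance_um: float = 2.0,
    image_id: str = "",
) -> DecoySet:
    """Place ``n_decoys`` non-overlapping background disks and measure their
    per-channel means exactly as cell means.

    Admissible centers are >= ``clearance_um + radius_um`` from any mask pixel
    and at least a radius from the border; centers are rejection-sampled
    uniformly over that support, and decoys may not overlap each other.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask)
    if stack.shape[1:] != mask.shape:
        raise ValueError("stack and mask shapes disagree")
    r_px = radius_um / pixel_size_um
    clear_px = (clearance_um + radius_um) / pixel_size_um
    # distance from each background pixel to the nearest cell pixel
    dist = ndimage.distance_transform_edt(mask == 0)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    admissible = (
        (dist >= clear_px)
        & (xx >= r_px) & (xx < w - r_px)
        & (yy >= r_px) & (yy < h - r_px)
    )
    cand = np.argwhere(admissible)  # (y, x)
    if len(cand) == 0:
        raise ValueError(f"no admissible background for decoys in image {image_id!r}")
    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int]] = []
    max_attempts = 10 * n_decoys
    attempts = 0
    while len(centers) < n_decoys and attempts < max_attempts:
        attempts += 1
        cy, cx = cand[rng.integers(len(cand))]
        if any((cx - px) ** 2 + (cy - py) ** 2 < (2 * r_px) ** 2 for px, py in centers):
            continue
        centers.append((int(cx), int(cy)))
    if len(centers) < n_decoys:
        raise ValueError(
            f"could only place {len(centers)}/{n_decoys} decoys in image {image_id!r}"
        )
    disk_y, disk_x = np.mgrid[-int(r_px) - 1 : int(r_px) + 2, -int(r_px) - 1 : int(r_px) + 2]
    in_disk = (disk_x + 0.0) ** 2 + (disk_y + 0.0) ** 2 <= r_px**2
    dy, dx = disk_y[in_disk], disk_x[in_disk]
    means = np.empty((len(centers), stack.shape[0]))
    for i, (cx, cy) in enumerate(centers):
        ys, xs = cy + dy, cx + dx
        means[i] = stack[:, ys, xs].mean(axis=1)
    return DecoySet(image_id=image_id, means=means,
                    centers=np.asarray(centers, dtype=float), radius_um=radius_um)


def subtract_background(cells: pd.DataFrame, decoys: DecoySet, channel_names) -> pd.DataFrame:
    """Subtract the mean decoy expression per channel, clipping at 0."""
    if decoys.means.shape[0] == 0:
        raise ValueError("decoy set is empty")
    out = cells.copy()
    bg = decoys.means.mean(axis=0)
    out[list(channel_names)] = np.clip(
        cells[list(channel_names)].to_numpy() - bg[None, :], 0.0, None
    )
    return out


def call_positive_cells(
    cells: pd.DataFrame,
    decoys: DecoySet,
    channel_names,
    fdr: float = 0.01,
    min_decoys: int = 50,
) -> pd.DataFrame:
    """Empirical positive-cell calls per channel against the decoy null.

    Each cell's p-value is (1 + #{decoy >= cell}) / (1 + n_decoys) on its raw
    channel value; Benjamini–Hochberg is applied across cells within each
    channel of the image, and a cell is positive where adjusted p <= ``fdr``.
    Returns a boolean DataFrame aligned with ``cells`` (one column/channel).
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    n_dec = decoys.means.shape[0]
    if n_dec < min_decoys:
        raise ValueError(f"need >= {min_decoys} decoys, got {n_dec}")
    flags = pd.DataFrame(False, index=cells.index, columns=list(channel_names))
    for ci, name in enumerate(channel_names):
        null = np.sort(decoys.means[:, ci])
        vals = cells[name].to_numpy()
        # #{decoy >= v} via position of v in the sorted null
        n_ge = n_dec - np.searchsorted(null, vals, side="left")
        pvals = (1.0 + n_ge) / (1.0 + n_dec)
        if len(pvals):
            rej, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
            flags[name] = rej
    return flags


def normalize_across_rois(
    cells: pd.DataFrame,
    positives: pd.DataFrame,
    channel_names,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale each (image, channel) so positive-cell medians agree across ROIs.

    factor = cohort-wide median of positive-cell values / image median of
    positive-cell values; images or channels with no positive cells (or zero
    median) pass through with factor 1. ``cells`` must carry an image_id
    column; returns (normalized cells, factor table image x channel).
    """
    cells = cells.copy()
    images = cells["image_id"].unique()
    factors = pd.DataFrame(1.0, index=images, columns=list(channel_names))
    for name in channel_names:
        pos_mask = positives[name].to_numpy()
        vals = cells[name].to_numpy()
        if not pos_mask.any():
            continue
        cohort_med = float(np.median(vals[pos_mask]))
        for img in images:
            in_img = (cells["image_id"] == img).to_numpy()
            sel = in_img & pos_mask
            if not sel.any():
                continue
            img_med = float(np.median(vals[sel]))
            if img_med > 0:
                f = cohort_med / img_med
                factors.loc[img, name] = f
                cells.loc[in_img, name] = vals[in_img] * f
    return cells, factors
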