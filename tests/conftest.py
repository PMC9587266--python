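import numpy as np
import pandas as pd
import pytest

import tmea


@pytest.fixture(scope="session")
def small_cohort() -> tmea.SyntheticCohort:
    """6-patient table-only cohort used across module tests."""
    cfg = tmea.CohortConfig(n_patients=6, cells_per_roi=500, seed=1)
    return tmea.generate_cohort(cfg)


@pytest.fixture(scope="session")
def rendered_roi():
    """One small rendered ROI: (config, cells-of-roi, stack, mask)."""
    cfg = tmea.CohortConfig(
        n_patients=1, rois_per_patient_ct=0, rois_per_patient_im=1,
        cells_per_roi=300, image_size_um=(300.0, 300.0), seed=5,
    )
    coh = tmea.generate_cohort(cfg, render=True)
    image_id = coh.meta["image_id"].iloc[0]
    cells = coh.cells[coh.cells["image_id"] == image_id].reset_index(drop=True)
    return cfg, cells, coh.images[image_id], coh.masks[image_id]


@pytest.fixture(scope="session")
def phenotyped(small_cohort) -> pd.DataFrame:
    out, _ = tmea.phenotype_cells(small_cohort.cells, seed=0)
    return out


def make_cells(xy: np.ndarray, labels=None) -> pd.DataFrame:
    """Minimal cell table from coordinates (µm)."""
    df = pd.DataFrame(np.asarray(xy, dtype=float), columns=["x_um", "y_um"])
    df["image_id"] = "img0"
    if labels is not None:
        df["subtype"] = list(labels)
    return df
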