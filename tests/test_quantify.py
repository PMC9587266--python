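"""Quantification: mean extraction, decoys, subtraction, calling, normalization."""

import numpy as np
import pandas as pd
import pytest

import tmea
from tmea.quantify import DecoySet


def _decoys(values: np.ndarray, image_id="img0") -> DecoySet:
    values = np.atleast_2d(values).T if np.asarray(values).ndim == 1 else values
    return DecoySet(image_id=image_id, means=np.asarray(values, dtype=float),
                    centers=np.zeros((len(values), 2)), radius_um=5.0)


class TestExtractCellMeans:
    def test_uniform_channel_gives_uniform_means(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:4, 2:4] = 1
        mask[6:9, 6:9] = 2
        stack = np.full((3, 10, 10), 7.0)
        out = tmea.extract_cell_means(stack, mask, ["a", "b", "c"])
        assert (out[["a", "b", "c"]].to_numpy() == 7.0).all()

    def test_two_pixel_cell_mean(self):
        mask = np.zeros((2, 2), dtype=int)
        mask[0, 0] = mask[0, 1] = 1
        stack = np.array([[[4.0, 6.0], [0.0, 0.0]]])
        out = tmea.extract_cell_means(stack, mask, ["m"])
        assert out.loc[0, "m"] == 5.0
        assert out.loc[0, "area"] == 2

    def test_shape_mismatch_and_empty_mask(self):
        with pytest.raises(ValueError):
            tmea.extract_cell_means(np.zeros((1, 4, 4)), np.zeros((5, 5), dtype=int), ["m"])
        out = tmea.extract_cell_means(np.zeros((1, 4, 4)), np.zeros((4, 4), dtype=int), ["m"])
        assert out.empty

    def test_matches_naive_pixel_loop(self, rendered_roi):
        """Bit-exact agreement with an independent per-pixel accumulation."""
        cfg, cells, stack, mask = rendered_roi
        out = tmea.extract_cell_means(stack, mask, cfg.panel.names)
        labels = np.unique(mask[mask > 0])
        for lab in labels[:20]:
            sel = mask == lab
            expected = stack.astype(float)[:, sel].mean(axis=1)
            got = out.loc[out.cell_id == lab, list(cfg.panel.names)].to_numpy()[0]
            assert np.array_equal(got, expected)


class TestDecoys:
    def test_full_mask_leaves_no_background(self):
        mask = np.ones((20, 20), dtype=int)
        with pytest.raises(ValueError, match="img7"):
            tmea.generate_decoys(np.zeros((1, 20, 20)), mask, n_decoys=5, image_id="img7")

    def test_constant_background_measured_exactly(self):
        mask = np.zeros((80, 80), dtype=int)
        stack = np.full((2, 80, 80), 3.0)
        d = tmea.generate_decoys(stack, mask, n_decoys=10, radius_um=4.0, seed=0)
        assert np.allclose(d.means, 3.0)

    def test_poisson_background_mean_recovered(self):
        rng = np.random.default_rng(0)
        lam = 2.5
        stack = rng.poisson(lam, size=(1, 200, 200)).astype(float)
        mask = np.zeros((200, 200), dtype=int)
        d = tmea.generate_decoys(stack, mask, n_decoys=60, radius_um=5.0, seed=1)
        n_px = np.pi * 25 * 60
        assert abs(d.means.mean() - lam) < 3 * np.sqrt(lam / n_px)

    def test_decoys_avoid_dilated_masks(self, rendered_roi):
        cfg, cells, stack, mask = rendered_roi
        d = tmea.generate_decoys(stack, mask, n_decoys=100, seed=2)
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(mask == 0)
        for cx, cy in d.centers.astype(int):
            assert dist[cy, cx] >= d.radius_um + 2.0


class TestSubtractBackground:
    def test_plain_subtraction_and_clip(self):
        cells = pd.DataFrame({"m": [10.0, 2.0]})
        out = tmea.subtract_background(cells, _decoys(np.full(50, 3.0)), ["m"])
        assert list(out["m"]) == [7.0, 0.0]

    def test_zero_decoy_mean_is_identity(self):
        cells = pd.DataFrame({"m": [1.5, 0.0]})
        out = tmea.subtract_background(cells, _decoys(np.zeros(50)), ["m"])
        assert list(out["m"]) == [1.5, 0.0]

    def test_empty_decoys_rejected(self):
        with pytest.raises(ValueError):
            tmea.subtract_background(pd.DataFrame({"m": [1.0]}), _decoys(np.zeros((0, 1))), ["m"])


class TestPositiveCalling:
    def test_cell_below_all_decoys_not_positive(self):
        cells = pd.DataFrame({"m": [0.1] * 20})
        flags = tmea.call_positive_cells(cells, _decoys(np.linspace(1, 2, 100)), ["m"])
        assert not flags["m"].any()

    def test_extreme_cell_survives_bh(self):
        """p = 1/1000 for a cell above 999 decoys; among 10 cells it passes
        BH at FDR 0.01 (adjusted p = 0.001 * 10 = 0.01)."""
        decoys = _decoys(np.linspace(0, 1, 999))
        cells = pd.DataFrame({"m": [2.0] + [0.0] * 9})
        flags = tmea.call_positive_cells(cells, decoys, ["m"])
        assert bool(flags["m"].iloc[0]) is True
        assert flags["m"].iloc[1:].sum() == 0

    def test_all_zero_channel_has_no_positives(self):
        cells = pd.DataFrame({"m": np.zeros(30)})
        flags = tmea.call_positive_cells(cells, _decoys(np.zeros(60)), ["m"])
        assert not flags["m"].any()

    def test_fdr_domain_checked(self):
        with pytest.raises(ValueError):
            tmea.call_positive_cells(pd.DataFrame({"m": [1.0]}), _decoys(np.zeros(60)),
                                     ["m"], fdr=1.5)

    def test_monotone_in_cell_value(self):
        """Raising one cell's value never removes its positive flag."""
        rng = np.random.default_rng(3)
        decoys = _decoys(rng.normal(0, 1, 200).clip(0))
        base = rng.normal(2, 1, 40).clip(0)
        cells = pd.DataFrame({"m": base})
        f0 = tmea.call_positive_cells(cells, decoys, ["m"])
        for i in np.where(f0["m"])[0][:5]:
            bumped = cells.copy()
            bumped.loc[i, "m"] += 1.0
            f1 = tmea.call_positive_cells(bumped, decoys, ["m"])
            assert bool(f1["m"].iloc[i])


class TestNormalization:
    def _cohort(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"image_id": "A", "m": rng.uniform(1, 3, 100)})
        b = a.copy()
        b["image_id"] = "B"
        b["m"] = a["m"] * 2
        cells = pd.concat([a, b], ignore_index=True)
        pos = pd.DataFrame({"m": [True] * len(cells)})
        return cells, pos

    def test_single_image_unit_factors(self):
        cells = pd.DataFrame({"image_id": "A", "m": [1.0, 2.0, 3.0]})
        pos = pd.DataFrame({"m": [True, True, True]})
        _, factors = tmea.normalize_across_rois(cells, pos, ["m"])
        assert np.allclose(factors, 1.0)

    def test_doubled_image_scaled_back(self):
        cells, pos = self._cohort()
        normed, factors = tmea.normalize_across_rois(cells, pos, ["m"])
        med_a = normed.loc[normed.image_id == "A", "m"].median()
        med_b = normed.loc[normed.image_id == "B", "m"].median()
        assert np.isclose(med_a, med_b)
        assert np.isclose(factors.loc["B", "m"] / factors.loc["A", "m"], 0.5)

    def test_idempotent(self):
        cells, pos = self._cohort()
        normed, _ = tmea.normalize_across_rois(cells, pos, ["m"])
        _, factors2 = tmea.normalize_across_rois(normed, pos, ["m"])
        assert (np.abs(factors2.to_numpy() - 1.0) < 1e-6).all()

    def test_lognormal_gain_variation_halved(self):
        """Per-ROI multiplicative gain ~ LogNormal(0, 0.3): normalization must
        cut the between-ROI spread of positive-cell medians by >= 50%."""
        rng = np.random.default_rng(5)
        frames = []
        for i in range(12):
            gain = rng.lognormal(0.0, 0.3)
            frames.append(pd.DataFrame(
                {"image_id": f"I{i}", "m": rng.uniform(1, 3, 200) * gain}))
        cells = pd.concat(frames, ignore_index=True)
        pos = pd.DataFrame({"m": [True] * len(cells)})
        meds0 = cells.groupby("image_id")["m"].median()
        normed, _ = tmea.normalize_across_rois(cells, pos, ["m"])
        meds1 = normed.groupby("image_id")["m"].median()
        cv0 = meds0.std() / meds0.mean()
        cv1 = meds1.std() / meds1.mean()
        assert cv1 <= 0.5 * cv0
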