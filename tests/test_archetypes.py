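"""Differential abundance, archetype clustering, voting, CIs, Cox models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

import tmea
from tmea.archetypes import ArchetypeModel


def _densities(n_r=10, n_nr=10, ratio=1.0, seed=0, base=0.05):
    rng = np.random.default_rng(seed)
    idx = [f"r{i}" for i in range(n_r)] + [f"n{i}" for i in range(n_nr)]
    resp = pd.Series(["R"] * n_r + ["NR"] * n_nr, index=idx)
    d = pd.DataFrame(
        {"ct": np.concatenate([rng.normal(base * ratio, base / 20, n_r),
                               rng.normal(base, base / 20, n_nr)]).clip(1e-4)},
        index=idx,
    )
    return d, resp


class TestDifferentialAbundance:
    def test_identical_groups_not_selected(self):
        d, resp = _densities(ratio=1.0)
        out = tmea.differential_abundance(d, resp)
        assert abs(out["log2fc"].iloc[0]) < 0.2
        assert not out["passes_selection"].iloc[0]

    def test_fourfold_enrichment_selected(self):
        d, resp = _densities(ratio=4.0)
        out = tmea.differential_abundance(d, resp)
        assert out["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.1)
        assert bool(out["passes_selection"].iloc[0])

    def test_low_density_types_excluded(self):
        d, resp = _densities(ratio=4.0, base=0.001)
        out = tmea.differential_abundance(d, resp)
        assert not out["passes_selection"].iloc[0]

    def test_selection_flag_is_pure_function_of_inputs(self):
        rng = np.random.default_rng(1)
        idx = [f"i{k}" for k in range(16)]
        resp = pd.Series(["R"] * 8 + ["NR"] * 8, index=idx)
        dens = pd.DataFrame(rng.dirichlet(np.ones(6), 16),
                            columns=list("abcdef"), index=idx)
        out = tmea.differential_abundance(dens, resp)
        expected = (
            (out["log2fc"].abs() >= 1.2)
            & (out["p_adj"] <= 0.05)
            & (out["overall_density"] >= 0.01)
        )
        assert (out["passes_selection"] == expected).all()

    def test_single_group_rejected(self):
        d, resp = _densities()
        with pytest.raises(ValueError):
            tmea.differential_abundance(d, pd.Series("R", index=d.index))


class TestClusterArchetypes:
    def _six_groups(self, reps=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        protos = np.eye(6) * 0.3 + 0.02
        rows, names = [], []
        for g in range(6):
            for r in range(reps):
                rows.append(protos[g] + rng.normal(0, noise, 6))
                names.append(f"g{g}_{r}")
        cols = ["B", "CD4+T", "CD8+T", "MC4", "MC2", "T1"]
        return pd.DataFrame(np.clip(rows, 0, None), index=names, columns=cols)

    def test_point_mass_groups_get_own_archetypes(self):
        dens = self._six_groups(noise=0.0)
        model = tmea.cluster_archetypes(dens, list(dens.columns), k=6)
        truth = [n.split("_")[0] for n in dens.index]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, model.roi_labels) == 1.0

    def test_duplicate_rois_share_archetype(self):
        dens = self._six_groups(noise=0.01, seed=2)
        dup = pd.concat([dens, dens.iloc[[0]].rename(index={dens.index[0]: "dup"})])
        model = tmea.cluster_archetypes(dup, list(dens.columns), k=6)
        assert model.roi_labels["dup"] == model.roi_labels[dens.index[0]]

    def test_complete_linkage_heights_match_hand_computation(self):
        """1-D points 0, 1, 3.5, 8: complete-linkage merges at 1, 3.5, 8."""
        from scipy.cluster import hierarchy

        x = np.array([[0.0], [1.0], [3.5], [8.0]])
        link = hierarchy.linkage(x, method="complete")
        assert np.allclose(link[:, 2], [1.0, 3.5, 8.0])

    def test_roi_order_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        dens = self._six_groups(noise=0.01, seed=3)
        perm = np.random.default_rng(0).permutation(len(dens))
        m1 = tmea.cluster_archetypes(dens, list(dens.columns), k=6)
        m2 = tmea.cluster_archetypes(dens.iloc[perm], list(dens.columns), k=6)
        assert adjusted_rand_score(m1.roi_labels.iloc[perm], m2.roi_labels) == 1.0

    def test_too_few_rois_rejected(self):
        dens = self._six_groups()[:4]
        with pytest.raises(ValueError):
            tmea.cluster_archetypes(dens, list(dens.columns), k=6)


class TestHotCold:
    def _model(self, profiles: dict[str, list[float]]) -> ArchetypeModel:
        cols = ["B", "CD4+T", "CD8+T", "MC4", "MC2", "T1"]
        z = pd.DataFrame(profiles, index=cols).T
        return ArchetypeModel(
            selected_types=cols, scale_mean=np.zeros(6), scale_sd=np.ones(6),
            linkage=np.empty((0, 4)), k=len(profiles),
            roi_labels=pd.Series(dtype=object), z_profiles=z,
        )

    def test_mc2_only_enrichment_is_cold(self):
        m = self._model({"A": [-1, -1, -1, -1, 2.0, -0.5]})
        assert tmea.assign_hot_cold(m)["A"] == "cold"

    def test_cd8_enrichment_is_hot(self):
        m = self._model({"A": [-0.5, -0.5, 1.5, -0.5, 0.0, 0.0]})
        assert tmea.assign_hot_cold(m)["A"] == "hot"

    def test_all_negative_profile_is_cold(self):
        m = self._model({"A": [-0.2] * 6})
        assert tmea.assign_hot_cold(m)["A"] == "cold"

    def test_override_wins(self):
        m = self._model({"A": [-0.2] * 6})
        assert tmea.assign_hot_cold(m, override={"A": "hot"})["A"] == "hot"


class TestVotePatients:
    def _meta(self, archetypes):
        return pd.DataFrame(
            {"image_id": [f"i{k}" for k in range(len(archetypes))],
             "patient": "P0", "region": "IM", "archetype": archetypes}
        )

    CAT = {"H1": "hot", "C1": "cold"}

    def test_majority_hot(self):
        out = tmea.vote_patients(self._meta(["H1", "H1", "C1"]), self.CAT)
        assert out.voted_category.iloc[0] == "hot" and not out.ties_resolved_hot.iloc[0]

    def test_tie_goes_hot(self):
        out = tmea.vote_patients(self._meta(["H1", "C1"]), self.CAT)
        assert out.voted_category.iloc[0] == "hot" and bool(out.ties_resolved_hot.iloc[0])

    def test_all_cold(self):
        out = tmea.vote_patients(self._meta(["C1", "C1", "C1"]), self.CAT)
        assert out.voted_category.iloc[0] == "cold"

    def test_patient_without_im_roi_dropped(self):
        meta = self._meta(["H1"])
        meta.loc[0, "region"] = "CT"
        assert tmea.vote_patients(meta, self.CAT).empty


class TestClassificationMetrics:
    def test_printed_contingency_arithmetic(self):
        roi_cat = pd.Series(["hot"] * 46 + ["cold"] * 12 + ["cold"] * 39 + ["hot"] * 2)
        roi_resp = pd.Series(["R"] * 58 + ["NR"] * 41)
        pat_cat = pd.Series(["hot"] * 11 + ["cold"] * 13)
        pat_resp = pd.Series(["R"] * 11 + ["R"] * 3 + ["NR"] * 10)
        out = tmea.classification_metrics(roi_cat, roi_resp, pat_cat, pat_resp)
        assert out["responder_roi_accuracy_pct"] == pytest.approx(79.31, abs=0.01)
        assert out["nonresponder_roi_accuracy_pct"] == pytest.approx(95.12, abs=0.01)
        assert out["orr_hot_pct"] == 100.0
        assert out["orr_cold_pct"] == pytest.approx(23.077, abs=0.01)

    def test_zero_rate(self):
        out = tmea.classification_metrics(
            pd.Series(["cold"] * 5), pd.Series(["NR"] * 5),
            pd.Series(["cold"] * 5), pd.Series(["NR"] * 5))
        assert out["orr_cold_pct"] == 0.0


class TestTlsEnrichment:
    def _meta(self, archetypes, tls=None):
        n = len(archetypes)
        return pd.DataFrame({"image_id": [f"i{k}" for k in range(n)],
                             "archetype": archetypes,
                             "tls": [True] * n if tls is None else tls})

    def test_seven_and_two_of_nine(self):
        out = tmea.tls_enrichment(self._meta(["H1"] * 7 + ["H3"] * 2)).set_index("archetype")
        assert out.loc["H1", "fraction"] == pytest.approx(7 / 9)
        assert (round(out.loc["H1", "ci_lower"], 2), round(out.loc["H1", "ci_upper"], 2)) == (0.40, 0.97)
        assert (round(out.loc["H3", "ci_lower"], 2), round(out.loc["H3", "ci_upper"], 2)) == (0.03, 0.60)

    def test_ci_matches_beta_quantile_oracle(self):
        out = tmea.tls_enrichment(self._meta(["H1"] * 7 + ["H3"] * 2)).set_index("archetype")
        x, n = 7, 9
        assert out.loc["H1", "ci_lower"] == pytest.approx(beta.ppf(0.025, x, n - x + 1), abs=1e-6)
        assert out.loc["H1", "ci_upper"] == pytest.approx(beta.ppf(0.975, x + 1, n - x), abs=1e-6)

    def test_no_tls_rois_empty(self):
        assert tmea.tls_enrichment(self._meta(["H1"], tls=[False])).empty


class TestCoxByCelltype:
    def _simulate(self, beta_true, n=200, seed=0):
        rng = np.random.default_rng(seed)
        dens = rng.uniform(0, 1, n)
        age = rng.normal(60, 8, n)
        t = rng.exponential(1.0 / np.exp(beta_true * dens), n)
        pats = [f"P{i}" for i in range(n)]
        densities = pd.DataFrame({"ct": dens}, index=pats)
        surv = pd.DataFrame({"patient": pats, "time": t, "event": 1, "age": age})
        return densities, surv

    def test_planted_log_hazard_recovered(self):
        densities, surv = self._simulate(beta_true=0.7)
        out = tmea.cox_by_celltype(densities, surv).iloc[0]
        se = (np.log(out.ci_upper) - np.log(out.ci_lower)) / (2 * 1.96)
        assert abs(np.log(out.hr) - 0.7) < 2 * se

    def test_null_coverage(self):
        covered = 0
        for s in range(40):
            densities, surv = self._simulate(beta_true=0.0, n=60, seed=s)
            out = tmea.cox_by_celltype(densities, surv).iloc[0]
            covered += out.ci_lower <= 1.0 <= out.ci_upper
        assert covered / 40 >= 0.90

    def test_constant_density_flagged(self):
        densities, surv = self._simulate(0.0)
        densities["ct"] = 0.5
        out = tmea.cox_by_celltype(densities, surv).iloc[0]
        assert out.flag == "constant density" and np.isnan(out.hr)
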