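"""Design construction, voxel-wise GLM, permutation FWE and region selection."""

import numpy as np
import pytest
from dataclasses import replace

import longicv as L
from longicv.iq_data import IQRecord, IQTable
from longicv.synthetic_cohort import make_ground_truth, simulate_iq, simulate_volumes
from longicv.vbm_glm import (
    CONTRASTS,
    Z_CAP,
    Contrast,
    MeasureThresholds,
    StatMap,
    build_design,
    extract_clusters,
    fit_contrast,
    fwe_thresholds_both,
    select_regions,
)


class TestDesign:
    def test_encoded_covariate_matches_hand_computation(self, tiny_table):
        design = build_design(tiny_table)
        # viq changes are (2, -1, 0, 3): encoding is -d at time 1, +d at time 2
        np.testing.assert_array_equal(
            design.matrix[:, -2], [-2, 2, 1, -1, 0, 0, -3, 3]
        )
        assert design.matrix.shape == (8, 7)
        assert design.df == 1

    def test_covariates_orthogonal_to_subject_indicators(self, table1):
        design = build_design(table1)
        n = design.n_subjects
        subj = design.matrix[:, :n]
        for k in range(3):
            np.testing.assert_allclose(subj.T @ design.matrix[:, n + k], 0, atol=1e-12)
        assert design.matrix[:, n].sum() == 0  # tau sums to zero

    def test_zero_change_cohort_flagged_degenerate(self):
        t = IQTable(tuple(IQRecord(i, 100 + i, 90 + i, 100 + i, 92 + i) for i in range(1, 6)))
        design = build_design(t)
        assert "e_viq" in design.degenerate

    def test_too_small_cohort_rejected(self):
        t = IQTable(tuple(IQRecord(i, 100, 90, 101, 91) for i in range(1, 4)))
        with pytest.raises(ValueError, match="n >= 4"):
            build_design(t)


class TestFitContrast:
    def test_equivalent_to_difference_model_ols(self, small_cohort):
        """Full 2N-scan GLM t equals the t of the change-score coefficient in
        the per-voxel difference regression — checked against statsmodels."""
        import statsmodels.api as sm

        table, truth, volumes = small_cohort
        design = build_design(table)
        diffs = volumes.differences().reshape(len(table), -1)
        X = sm.add_constant(np.column_stack([table.changes("viq"), table.changes("piq")]))
        for name, col in (("viq", 1), ("piq", 2), ("v_minus_p", None)):
            stat = fit_contrast(volumes, design, Contrast(CONTRASTS[name], name))
            for v in range(0, diffs.shape[1], 37):  # stride across the volume
                fit = sm.OLS(diffs[:, v], X).fit()
                if col is not None:
                    expected = fit.tvalues[col]
                else:
                    expected = fit.t_test([0, 1, -1]).tvalue.item()
                assert stat.t_values.ravel()[v] == pytest.approx(expected, abs=1e-8)

    def test_degrees_of_freedom(self, small_cohort):
        table, _, volumes = small_cohort
        stat = fit_contrast(volumes, build_design(table), Contrast(CONTRASTS["viq"], "viq"))
        assert stat.df == len(table) - 3

    def test_null_voxelwise_false_positive_rate(self):
        """With no planted effect the one-sided p < 0.05 rate is nominal."""
        rates = []
        for s in range(20):
            t = simulate_iq(15, seed=50 + s)
            truth = make_ground_truth(shape=(10, 10, 10), region_radius_vox=1.5,
                                      noise_sd=1.0, seed=s)
            vols = simulate_volumes(t, truth, seed=80 + s)
            stat = fit_contrast(vols, build_design(t), Contrast(CONTRASTS["viq"], "viq"))
            from scipy import stats as sps

            crit = sps.t.isf(0.05, stat.df)
            rates.append(np.mean(stat.t_values >= crit))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.015)

    def test_perfect_fit_reports_capped_z(self, tiny_table):
        truth = make_ground_truth(shape=(6, 6, 6), region_radius_vox=0.9,
                                  center_v=(1, 3, 3), center_p=(4, 3, 3),
                                  noise_sd=0.0, slope_v=0.01, seed=1)
        vols = simulate_volumes(tiny_table, truth, seed=2)
        stat = fit_contrast(vols, build_design(tiny_table), Contrast(CONTRASTS["viq"], "viq"))
        assert np.isinf(stat.t_values[truth.center_v])
        assert stat.z_values[truth.center_v] == Z_CAP

    def test_rank_deficient_design_rejected(self):
        t = IQTable(tuple(IQRecord(i, 100 + i, 90 + i, 100 + i, 92 + i) for i in range(1, 6)))
        truth = make_ground_truth(shape=(6, 6, 6), region_radius_vox=0.9,
                                  center_v=(1, 3, 3), center_p=(4, 3, 3), seed=1)
        vols = simulate_volumes(t, truth, seed=3)
        with pytest.raises(ValueError, match="e_viq"):
            fit_contrast(vols, build_design(t), Contrast(CONTRASTS["viq"], "viq"))

    def test_subject_order_mismatch_rejected(self, small_cohort):
        table, _, volumes = small_cohort
        from longicv.iq_data import IQTable

        design = build_design(IQTable(tuple(reversed(table.records))))
        with pytest.raises(ValueError, match="order"):
            fit_contrast(volumes, design, Contrast(CONTRASTS["viq"], "viq"))


def _stat_map_from(t_values):
    t_values = np.asarray(t_values, dtype=float)
    return StatMap(
        t_values=t_values,
        z_values=t_values.copy(),
        df=30,
        contrast=Contrast((0, 1, 0), "viq"),
        voxel_size=1.0,
        affine=np.eye(4),
    )


class TestClusterExtraction:
    def test_two_planted_blobs(self):
        t = np.zeros((8, 8, 8))
        blob1 = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1), (1, 2, 2)]
        blob2 = [(6, 6, 6), (6, 6, 5), (6, 5, 6), (5, 6, 6), (6, 5, 5)]
        for v in blob1:
            t[v] = 4.0
        t[1, 1, 1] = 5.0
        for v in blob2:
            t[v] = 4.5
        t[6, 6, 6] = 6.0
        clusters = extract_clusters(_stat_map_from(t), 3.0)
        assert len(clusters) == 2
        assert [c.size for c in clusters] == [5, 5]
        assert clusters[0].peak == (6, 6, 6) and clusters[0].peak_t == 6.0
        assert clusters[1].peak == (1, 1, 1)
        assert set(clusters[1].voxels) == set(blob1)

    def test_sub_threshold_map_yields_nothing(self):
        assert extract_clusters(_stat_map_from(np.ones((4, 4, 4))), 2.0) == []

    def test_tie_breaks_to_smallest_linear_index_x_fastest(self):
        t = np.zeros((4, 4, 4))
        t[2, 1, 0] = 5.0  # F-order linear index 2 + 4*1 = 6
        t[1, 0, 1] = 5.0  # F-order linear index 1 + 16 = 17 -> larger
        t[2, 0, 0] = 4.0  # bridge keeping them in one cluster under 26-conn
        t[1, 1, 0] = 4.0
        clusters = extract_clusters(_stat_map_from(t), 3.9)
        assert len(clusters) == 1
        assert clusters[0].peak == (2, 1, 0)

    @pytest.mark.parametrize("connectivity,expected", [(6, 2), (26, 1)])
    def test_connectivity_modes(self, connectivity, expected):
        t = np.zeros((4, 4, 4))
        t[1, 1, 1] = 5.0
        t[2, 2, 2] = 5.0  # diagonal neighbour: joined only under 26-connectivity
        clusters = extract_clusters(_stat_map_from(t), 4.0, connectivity=connectivity)
        assert len(clusters) == expected


class TestFWEThresholds:
    def test_constant_zero_volumes_never_exceed_height(self, tiny_table):
        shape = (6, 6, 6)
        vols = L.CohortVolumes(
            subject_ids=tuple(tiny_table.subject_ids),
            vol_t1=np.zeros((4, *shape)),
            vol_t2=np.zeros((4, *shape)),
            voxel_size=3.0,
            affine=np.eye(4),
        )
        design = build_design(tiny_table)
        th = fwe_thresholds_both(vols, design, n_perm=100, seed=1,
                                 cluster_forming_p={"viq": 0.001, "piq": 0.01})
        stat = fit_contrast(vols, design, Contrast(CONTRASTS["viq"], "viq"))
        assert not np.any(stat.t_values > th["viq"].height_t_crit)

    def test_n_perm_too_small_rejected(self, small_cohort):
        table, _, volumes = small_cohort
        with pytest.raises(ValueError, match="n_perm"):
            fwe_thresholds_both(volumes, build_design(table), n_perm=50, seed=1,
                                cluster_forming_p={"viq": 0.001, "piq": 0.01})

    def test_height_threshold_decreases_with_smoothness(self):
        """Smoother noise means fewer independent tests, hence a lower
        max-t critical value (paired null cohorts, directional check)."""
        crits = []
        for fwhm in (3.0, 12.0):
            t = simulate_iq(16, seed=14)
            truth = make_ground_truth(shape=(12, 12, 12), region_radius_vox=1.5,
                                      noise_sd=1.0, smooth_fwhm=fwhm, seed=5)
            vols = simulate_volumes(t, truth, seed=15)
            th = fwe_thresholds_both(vols, build_design(t), n_perm=200, seed=6,
                                     cluster_forming_p={"viq": 0.001, "piq": 0.01})
            crits.append(th["viq"].height_t_crit)
        assert crits[1] < crits[0]


class TestSelectRegions:
    def _maps_and_thresholds(self, table, volumes, n_perm=120, seed=9):
        design = build_design(table)
        maps = {k: fit_contrast(volumes, design, Contrast(w, k)) for k, w in CONTRASTS.items()}
        th = fwe_thresholds_both(volumes, design, n_perm=n_perm, seed=seed,
                                 cluster_forming_p={"viq": 0.001, "piq": 0.01})
        return maps, th

    def test_recovers_planted_disjoint_regions(self, strong_cohort):
        table, truth, volumes = strong_cohort
        maps, th = self._maps_and_thresholds(table, volumes)
        sel = select_regions(maps, th)
        for m in ("viq", "piq"):
            top = sel.top(m)
            assert top is not None and not sel.type2_flag[m]
            assert truth.region(m)[top.cluster.peak]
            assert top.basis in ("height-FWE", "extent-FWE")

    def test_shared_effect_removed_by_conjunction(self):
        """A region coupled identically to both measures fails the V-P / P-V
        difference conjunction and is dropped from both selections."""
        table = simulate_iq(33, seed=33)
        truth = make_ground_truth(shape=(12, 12, 12), region_radius_vox=1.5,
                                  noise_sd=0.3, slope_v=0.05, seed=7)
        volumes = simulate_volumes(table, truth, seed=34)
        # add an equally strong PIQ coupling on the *same* region
        bump = truth.slope_v * np.where(truth.region_v, 1.0, 0.0)
        d_p = table.changes("piq")
        vol_t1 = volumes.vol_t1 - bump * d_p[:, None, None, None]
        vol_t2 = volumes.vol_t2 + bump * d_p[:, None, None, None]
        volumes = replace(volumes, vol_t1=vol_t1, vol_t2=vol_t2)
        maps, th = self._maps_and_thresholds(table, volumes)
        # the main effects are overwhelming ...
        assert maps["viq"].t_values[truth.center_v] > th["viq"].height_t_crit
        sel = select_regions(maps, th)
        # ... yet the conjunction removes the shared region from both selections
        assert sel.clusters["viq"] == [] and sel.clusters["piq"] == []

    def test_null_with_search_mask_falls_back(self):
        table = simulate_iq(20, seed=41)
        truth = make_ground_truth(shape=(12, 12, 12), region_radius_vox=1.5,
                                  noise_sd=1.0, seed=8)  # no planted slopes
        volumes = simulate_volumes(table, truth, seed=141)
        maps, th = self._maps_and_thresholds(table, volumes)
        mask = L.synthetic_cohort.search_mask_around_truth(truth, margin_vox=3)
        sel = select_regions(maps, th, search_mask=mask)
        for m in ("viq", "piq"):
            top = sel.top(m)
            assert sel.type2_flag[m] and top is not None
            assert top.basis == "search-space-max"
            assert mask[top.cluster.peak]

    def test_empty_mask_rejected(self, strong_cohort):
        table, truth, volumes = strong_cohort
        maps, th = self._maps_and_thresholds(table, volumes)
        with pytest.raises(ValueError, match="mask"):
            select_regions(maps, th, search_mask=np.zeros(truth.shape, dtype=bool))
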