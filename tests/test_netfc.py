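"""Network FC statistics: extraction, correlation, averaging, group tests."""

import numpy as np
import pandas as pd
import pytest
from conftest import brute_force_bh_reject
from hypothesis import given, settings
from hypothesis import strategies as st

from visionet import (
    AtlasNetworks,
    Bold4D,
    NetworkConnectivityMeasure,
    RoiFCMatrix,
    RoiTimeSeries,
    chi_square_2x2,
    compare_groups,
    correlate_clinical,
    extract_roi_timeseries,
    fdr_bh,
    fisher_z,
    network_matrix,
    pearson_r,
    roi_fc_matrix,
    ttest_from_summary,
    ttest_two_sample,
)


def _mini_atlas(assignment):
    """One voxel per ROI along the x axis (plus background padding)."""
    n = len(assignment)
    labels = np.zeros((n + 2, 3, 3), dtype=int)
    for i, roi in enumerate(sorted(assignment)):
        labels[i + 1, 1, 1] = roi
    return AtlasNetworks(labels=labels, assignment=assignment, affine=np.eye(4))


def _zmatrix(z_entries, n):
    z = np.zeros((n, n))
    r = np.zeros((n, n))
    for (i, j), v in z_entries.items():
        z[i, j] = z[j, i] = v
        r[i, j] = r[j, i] = np.tanh(v)
    np.fill_diagonal(r, 1.0)
    return RoiFCMatrix(r=r, z=z, roi_ids=list(range(1, n + 1)))


class TestRoiExtraction:
    def test_unweighted_mean_over_voxels(self):
        labels = np.zeros((4, 1, 1), dtype=int)
        labels[0:2, 0, 0] = 1
        atlas = AtlasNetworks(labels=labels, assignment={1: "PVN"}, affine=np.eye(4))
        data = np.zeros((4, 1, 1, 2))
        data[0, 0, 0] = [1.0, 10.0]
        data[1, 0, 0] = [3.0, 20.0]
        run = Bold4D(data=data, affine=np.eye(4), tr=2.0)
        ts = extract_roi_timeseries(run, atlas)
        assert np.allclose(ts.matrix, [[2.0, 15.0]])

    def test_single_voxel_roi_is_identity(self):
        atlas = _mini_atlas({1: "PVN", 2: "HVN"})
        rng = np.random.default_rng(0)
        data = rng.standard_normal((*atlas.labels.shape, 6))
        run = Bold4D(data=data, affine=np.eye(4), tr=2.0)
        ts = extract_roi_timeseries(run, atlas)
        assert np.allclose(ts.matrix[0], data[1, 1, 1])

    def test_voxel_order_invariance(self):
        labels = np.zeros((4, 1, 1), dtype=int)
        labels[[0, 2], 0, 0] = 1
        atlas = AtlasNetworks(labels=labels, assignment={1: "PVN"}, affine=np.eye(4))
        data = np.zeros((4, 1, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[2, 0, 0] = [7, 8, 9]
        swapped = data.copy()
        swapped[[0, 2]] = swapped[[2, 0]]
        a = extract_roi_timeseries(Bold4D(data, np.eye(4), 2.0), atlas)
        b = extract_roi_timeseries(Bold4D(swapped, np.eye(4), 2.0), atlas)
        assert np.allclose(a.matrix, b.matrix)

    def test_empty_roi_named_in_error(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 1, 1] = 1
        atlas = AtlasNetworks(
            labels=labels, assignment={1: "PVN", 2: "HVN"}, affine=np.eye(4)
        )
        run = Bold4D(np.zeros((3, 3, 3, 5)), np.eye(4), 2.0)
        with pytest.raises(ValueError, match="ROI 2"):
            extract_roi_timeseries(run, atlas)

    def test_grid_mismatch_rejected(self):
        atlas = _mini_atlas({1: "PVN"})
        run = Bold4D(np.zeros((5, 5, 5, 4)), np.eye(4), 2.0)
        with pytest.raises(ValueError, match="match"):
            extract_roi_timeseries(run, atlas)


class TestPearsonAndFisher:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_correlations(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_fisher_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_fisher_odd(self):
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3))

    def test_fisher_clamps_unit_correlation_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            z = fisher_z(1.0)
        assert np.isfinite(z) and z > 8


class TestNetworkMatrix:
    def test_two_roi_network_intra_is_single_pair(self):
        atlas = _mini_atlas({1: "PVN", 2: "PVN", 3: "HVN"})
        fc = _zmatrix({(0, 1): 0.5, (0, 2): 0.2, (1, 2): 0.4}, 3)
        mat = network_matrix(fc, atlas)
        assert mat.loc["PVN", "PVN"] == pytest.approx(0.5)
        assert mat.loc["PVN", "HVN"] == pytest.approx(0.3)  # mean(0.2, 0.4)

    def test_single_roi_network_intra_missing(self):
        atlas = _mini_atlas({1: "PVN", 2: "PVN", 3: "HVN"})
        fc = _zmatrix({(0, 1): 0.5, (0, 2): 0.2, (1, 2): 0.4}, 3)
        mat = network_matrix(fc, atlas)
        assert np.isnan(mat.loc["HVN", "HVN"])

    def test_constant_z_gives_constant_entries(self):
        atlas = _mini_atlas({1: "PVN", 2: "PVN", 3: "HVN", 4: "HVN", 5: "VSN", 6: "VSN"})
        entries = {(i, j): 0.7 for i in range(6) for j in range(i + 1, 6)}
        mat = network_matrix(_zmatrix(entries, 6), atlas)
        assert np.allclose(mat.to_numpy(), 0.7)

    def test_invariant_to_roi_relabelling_within_networks(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(-0.5, 0.5, size=(6, 6))
        entries = {(i, j): raw[i, j] for i in range(6) for j in range(i + 1, 6)}
        nets = {1: "PVN", 2: "PVN", 3: "HVN", 4: "HVN", 5: "VSN", 6: "VSN"}
        mat = network_matrix(_zmatrix(entries, 6), _mini_atlas(nets))
        # swap ROI 1 and 2 (both PVN): permute the fc matrix accordingly
        perm = [1, 0, 2, 3, 4, 5]
        entries_p = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])): v
            for (i, j), v in entries.items()
        }
        mat_p = network_matrix(_zmatrix(entries_p, 6), _mini_atlas(nets))
        assert np.allclose(mat.to_numpy(), mat_p.to_numpy())

    def test_entries_bounded_by_constituent_pairs(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(-1.0, 1.0, size=(6, 6))
        entries = {(i, j): raw[i, j] for i in range(6) for j in range(i + 1, 6)}
        nets = {1: "PVN", 2: "PVN", 3: "HVN", 4: "HVN", 5: "VSN", 6: "VSN"}
        fc = _zmatrix(entries, 6)
        mat = network_matrix(fc, _mini_atlas(nets))
        all_z = [v for v in entries.values()]
        assert mat.to_numpy().max() <= max(all_z) + 1e-12
        assert mat.to_numpy().min() >= min(all_z) - 1e-12

    def test_unassigned_roi_rejected(self):
        atlas = _mini_atlas({1: "PVN", 2: "PVN"})
        fc = _zmatrix({(0, 1): 0.5, (0, 2): 0.1, (1, 2): 0.1}, 3)
        with pytest.raises(ValueError, match="assignment"):
            network_matrix(fc, atlas)


class TestGroupTests:
    def test_age_comparison_from_printed_summaries(self):
        _, p = ttest_from_summary(51.65, 11.25, 20, 51.00, 10.13, 20)
        assert round(p, 2) == 0.85

    def test_vsn_intra_row_from_printed_summaries(self):
        _, p = ttest_from_summary(0.3092, 0.0825, 20, 0.3293, 0.1160, 20)
        assert p == pytest.approx(0.5326, abs=0.01)

    def test_identical_groups_null(self):
        t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance(self):
        assert ttest_two_sample([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        with pytest.raises(ValueError, match="zero pooled variance"):
            ttest_two_sample([2.0, 2.0], [3.0, 3.0])

    def test_chi_square_homogeneous(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_chi_square_sex_table(self):
        stat, _ = chi_square_2x2([[11, 9], [14, 6]])
        assert stat == pytest.approx(0.96, abs=1e-9)

    def test_chi_square_scales_linearly_with_counts(self):
        s1, _ = chi_square_2x2([[11, 9], [14, 6]])
        s2, _ = chi_square_2x2([[22, 18], [28, 12]])
        assert s2 == pytest.approx(2 * s1)

    def test_chi_square_zero_marginal(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 5], [0, 7]])


class TestFDR:
    def test_step_up_hand_example(self):
        adjusted, reject = fdr_bh([0.01, 0.02, 0.5], alpha=0.05)
        assert np.allclose(adjusted, [0.03, 0.03, 0.5])
        assert list(reject) == [True, True, False]

    def test_single_p_unchanged(self):
        adjusted, _ = fdr_bh([0.031])
        assert adjusted[0] == pytest.approx(0.031)

    def test_ties_all_equal(self):
        adjusted, _ = fdr_bh([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adjusted, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_rejection_set_matches_definition(self, pvals, alpha):
        _, reject = fdr_bh(pvals, alpha=alpha)
        assert list(reject) == list(brute_force_bh_reject(np.array(pvals), alpha))


def _matrices_from(values):
    nets = ["PVN", "HVN", "VSN"]
    return [pd.DataFrame(v, index=nets, columns=nets) for v in values]


class TestCompareGroups:
    def _cohort(self, rng, shift=None, n=15):
        base = np.array([[0.8, 0.3, 0.1], [0.3, 0.45, 0.13], [0.1, 0.13, 0.33]])
        if shift is not None:
            base = base + shift
        mats = []
        for _ in range(n):
            noise = rng.normal(0, 0.08, size=(3, 3))
            noise = (noise + noise.T) / 2
            mats.append(base + noise)
        return _matrices_from(mats)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(0)
        a, b = self._cohort(rng), self._cohort(rng)
        fwd = compare_groups(a, b).table
        rev = compare_groups(b, a).table
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p_raw"], rev["p_raw"])

    def test_reduced_inter_pairs_flagged_not_intra(self):
        rng = np.random.default_rng(1)
        shift = np.zeros((3, 3))
        shift[0, 1] = shift[1, 0] = -0.3  # PVN-HVN
        shift[1, 2] = shift[2, 1] = -0.3  # HVN-VSN
        patients = self._cohort(rng, shift=shift, n=20)
        controls = self._cohort(rng, n=20)
        table = compare_groups(patients, controls).table.set_index("pair")
        assert table.loc["PVN-HVN", "significant"]
        assert table.loc["HVN-VSN", "significant"]
        assert not table.loc[["PVN", "HVN", "VSN"], "significant"].any()

    def test_difference_matrix_is_patient_minus_control(self):
        rng = np.random.default_rng(2)
        a, b = self._cohort(rng), self._cohort(rng)
        comp = compare_groups(a, b)
        expected = np.mean([m.to_numpy() for m in a], axis=0) - np.mean(
            [m.to_numpy() for m in b], axis=0
        )
        assert np.allclose(comp.difference.to_numpy(), expected)
        assert np.allclose(comp.difference.to_numpy(), comp.difference.to_numpy().T)

    def test_fdr_within_families(self):
        rng = np.random.default_rng(3)
        a, b = self._cohort(rng), self._cohort(rng)
        table = compare_groups(a, b).table
        assert set(table["family"]) == {"intra", "inter"}
        assert len(table) == 6

    def test_inconsistent_ordering_rejected(self):
        rng = np.random.default_rng(4)
        a, b = self._cohort(rng), self._cohort(rng)
        bad = a[0].iloc[::-1, ::-1]
        with pytest.raises(ValueError, match="ordering"):
            compare_groups([bad, *a[1:]], b)


class TestClinicalCorrelation:
    def test_perfect_line(self):
        fc = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = correlate_clinical(fc, 2 * fc + 1)
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["significant"]

    def test_sign_symmetry(self):
        rng = np.random.default_rng(5)
        fc = rng.standard_normal(20)
        cov = rng.standard_normal(20) + 0.4 * fc
        a = correlate_clinical(fc, cov)
        b = correlate_clinical(fc, -cov)
        assert a["r"] == pytest.approx(-b["r"])
        assert a["slope"] == pytest.approx(-b["slope"])

    def test_null_calibration(self):
        """Independent draws at n=20: ~5% of repetitions reach p < 0.05."""
        rng = np.random.default_rng(6)
        hits = sum(
            correlate_clinical(rng.standard_normal(20), rng.standard_normal(20))[
                "significant"
            ]
            for _ in range(400)
        )
        assert 0.02 <= hits / 400 <= 0.09

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_clinical([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])


class TestNetworkConnectivityMeasureTransformer:
    def test_transform_matches_functional_path(self, tiny_atlas):
        rng = np.random.default_rng(7)
        series = rng.standard_normal((19, 60))
        ts = RoiTimeSeries(matrix=series, roi_ids=tiny_atlas.roi_ids, tr=2.0)
        ref = network_matrix(roi_fc_matrix(ts), tiny_atlas)
        measure = NetworkConnectivityMeasure(atlas=tiny_atlas).fit()
        (out,) = measure.transform([series.T])  # time x roi convention
        pd.testing.assert_frame_equal(out, ref)

    def test_requires_atlas(self):
        with pytest.raises(ValueError, match="Atlas"):
            NetworkConnectivityMeasure().fit()
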