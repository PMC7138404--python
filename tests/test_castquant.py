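import numpy as np
import pytest

from vasokin import (analyze_skeleton, interpolate_roi, qc_concordance,
                     quantify_cast, resample_isotropic, segment_vessels,
                     skeletonize_vessels)
from vasokin import synthetic
from vasokin.castquant import count_segments
from vasokin.thinning import thin_3d


def _tube_stack(tubes, shape):
    stack, truth = synthetic.generate_cast_phantom(tubes, shape)
    return stack, truth


class TestResampling:
    def test_constant_image_unchanged(self):
        out = resample_isotropic(np.full((4, 8, 8), 7.0))
        np.testing.assert_array_equal(out, 7.0)
        assert out.shape == (4, 4, 4)

    def test_checkerboard_averages_to_uniform(self):
        z = np.indices((2, 8, 8)).sum(axis=0) % 2
        out = resample_isotropic(z.astype(float))
        np.testing.assert_allclose(out, 0.5)

    def test_tube_volume_conserved(self):
        # rasterise at 14 um in-plane, aggregate to 28 um: intensity-weighted
        # volume is conserved within 5%
        stack, _ = _tube_stack(
            [synthetic.Tube((100, 500, 500), (2700, 500, 500), 70.0)],
            (100, 36, 36))
        fine = np.repeat(np.repeat(stack, 2, axis=1), 2, axis=2)
        coarse = resample_isotropic(fine)
        assert coarse.sum() == pytest.approx(fine.sum() / 4, rel=1e-12)
        assert (coarse > 0).sum() * 28 ** 3 == pytest.approx(
            (stack > 0).sum() * 28 ** 3, rel=0.05)


class TestROIInterpolation:
    def _circle(self, r, shape=(40, 40), c=(20, 20)):
        yy, xx = np.indices(shape)
        return np.hypot(yy - c[0], xx - c[1]) <= r

    def test_annotated_slices_reproduced_exactly(self):
        rois = {2: self._circle(8), 10: self._circle(14)}
        mask = interpolate_roi(rois, 13, (40, 40))
        np.testing.assert_array_equal(mask[2], rois[2])
        np.testing.assert_array_equal(mask[10], rois[10])

    def test_identical_circles_give_cylinder(self):
        rois = {0: self._circle(8), 6: self._circle(8)}
        mask = interpolate_roi(rois, 7, (40, 40))
        for z in range(7):
            np.testing.assert_array_equal(mask[z], rois[0])

    def test_growing_circle_monotone_area(self):
        rois = {0: self._circle(5), 10: self._circle(15)}
        mask = interpolate_roi(rois, 11, (40, 40))
        areas = mask.sum(axis=(1, 2))
        assert np.all(np.diff(areas) > 0)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            interpolate_roi({3: self._circle(5)}, 10, (40, 40))


class TestSegmentation:
    def test_bright_tube_retained(self):
        stack, _ = _tube_stack(
            [synthetic.Tube((100, 500, 500), (2700, 500, 500), 70.0)],
            (100, 36, 36))
        vessel = segment_vessels(stack)
        np.testing.assert_array_equal(vessel, stack > 0)

    def test_small_speckles_removed(self, rng):
        stack = np.zeros((30, 30, 30))
        for _ in range(5):  # 8-voxel speckles, far below the 500 threshold
            z, y, x = rng.integers(2, 26, 3)
            stack[z:z + 2, y:y + 2, x:x + 2] = 200.0
        assert not segment_vessels(stack).any()

    def test_gap_bridged_by_closing(self):
        stack = np.zeros((60, 20, 20))
        stack[5:30, 8:12, 8:12] = 200.0
        stack[31:56, 8:12, 8:12] = 200.0  # one-voxel gap at z=30
        vessel = segment_vessels(stack, volume_threshold_voxels=100)
        from scipy import ndimage
        _, n = ndimage.label(vessel, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = segment_vessels(np.zeros((10, 10, 10)))
        assert not out.any()


class TestSkeleton:
    def test_straight_cylinder_gives_single_centerline(self):
        stack, _ = _tube_stack(
            [synthetic.Tube((100, 500, 500), (2700, 500, 500), 56.0)],
            (100, 36, 36))
        skel = skeletonize_vessels(stack > 0)
        assert count_segments(skel) == 1
        # one-voxel-wide: no skeleton voxel has more than 2 neighbours
        from vasokin.castquant import _neighbor_counts
        assert _neighbor_counts(skel)[skel].max() <= 2

    def test_skeleton_of_empty_map_is_empty(self):
        assert not skeletonize_vessels(np.zeros((5, 5, 5), bool)).any()

    def test_skeleton_subset_and_component_preserving(self):
        stack, _ = _tube_stack(
            [synthetic.Tube((100, 400, 400), (2700, 400, 400), 56.0),
             synthetic.Tube((100, 1000, 400), (2700, 1000, 400), 56.0)],
            (100, 52, 30))
        v = stack > 0
        skel = skeletonize_vessels(v)
        assert np.all(v[skel])
        from scipy import ndimage
        s26 = np.ones((3, 3, 3))
        assert ndimage.label(skel, structure=s26)[1] == \
            ndimage.label(v, structure=s26)[1] == 2

    def test_torus_thins_to_closed_loop(self):
        z, y, x = np.mgrid[0:9, 0:30, 0:30]
        ring = np.hypot(np.hypot(y - 14.5, x - 14.5) - 8, z - 4) <= 2.5
        skel = thin_3d(ring)
        from vasokin.castquant import _neighbor_counts
        nb = _neighbor_counts(skel)
        assert skel.any()
        assert np.all(nb[skel] == 2)  # every loop voxel has two neighbours
        assert count_segments(skel) == 1


class TestCounting:
    def test_y_junction_counts_three_branches(self):
        c = (1400.0, 700.0, 700.0)
        stack, _ = _tube_stack(
            [synthetic.Tube(c, (2600, 700, 700), 56.0),
             synthetic.Tube(c, (200, 1300, 700), 56.0),
             synthetic.Tube(c, (200, 100, 700), 56.0)], (110, 60, 50))
        stats, _, _ = quantify_cast(stack)
        assert stats.n_segments == 3

    def test_disjoint_tubes_add_up(self):
        tubes = [synthetic.Tube((100, 400, 700), (2900, 400, 700), 56.0),
                 synthetic.Tube((100, 1000, 700), (2900, 1000, 700), 56.0)]
        stats, _, _ = quantify_cast(_tube_stack(tubes, (110, 60, 50))[0])
        assert stats.n_segments == 2

    def test_density_formula_identity(self):
        stack, _ = _tube_stack(
            [synthetic.Tube((100, 700, 700), (2900, 700, 700), 56.0)],
            (110, 50, 50))
        stats, _, _ = quantify_cast(stack)
        voxvol = (stats.voxel_size_um / 1000.0) ** 3
        assert stats.vessel_density_per_mm3 * stats.mask_voxels * voxvol \
            == pytest.approx(stats.n_segments, rel=1e-12)

    def test_rotation_invariant_counts(self):
        c = (1400.0, 700.0, 700.0)
        stack, _ = _tube_stack(
            [synthetic.Tube(c, (2600, 700, 700), 56.0),
             synthetic.Tube(c, (200, 1300, 700), 56.0),
             synthetic.Tube(c, (200, 100, 700), 56.0)], (110, 60, 50))
        base = quantify_cast(stack)[0].n_segments
        for axes in [(0, 1), (0, 2), (1, 2)]:
            rot = quantify_cast(np.rot90(stack, axes=axes))[0].n_segments
            assert rot == base

    def test_component_definition_switch(self):
        c = (1400.0, 700.0, 700.0)
        stack, _ = _tube_stack(
            [synthetic.Tube(c, (2600, 700, 700), 56.0),
             synthetic.Tube(c, (200, 1300, 700), 56.0),
             synthetic.Tube(c, (200, 100, 700), 56.0)], (110, 60, 50))
        skel = skeletonize_vessels(segment_vessels(stack))
        assert count_segments(skel, segment_definition="components") == 1
        assert count_segments(skel, segment_definition="branches") == 3

    def test_vvf_within_ten_percent_of_analytic(self):
        tube = synthetic.Tube((100, 700, 700), (2900, 700, 700), 56.0)
        stack, truth = _tube_stack([tube], (110, 50, 50))
        stats, _, _ = quantify_cast(stack)
        analytic = truth.params["vessel_volume_um3"] / \
            truth.params["tumor_mask_volume_um3"]
        assert stats.vascular_volume_fraction == pytest.approx(
            analytic, rel=0.10)


class TestConcordanceQC:
    def test_equal_fractions_included(self):
        qc = qc_concordance([2.0, 2.1], [70.0, 72.0])
        assert list(qc["decision"]) == ["include", "include"]

    def test_grossly_underfilled_excluded(self):
        qc = qc_concordance([2.0, 2.0, 0.2], [70.0, 70.0, 70.0])
        assert list(qc["decision"]) == ["include", "include", "exclude"]

    def test_missing_mri_is_undetermined(self):
        qc = qc_concordance([2.0, 2.0], [70.0, np.nan])
        assert qc["decision"][1] == "undetermined"

    def test_synthetic_cohort_exclusions_match_truth(self):
        coh = synthetic.generate_qc_cohort(10, 3, seed=7)
        qc = qc_concordance(coh["cast_vvf"], coh["mri_perfused_pct"])
        np.testing.assert_array_equal(qc["decision"] == "exclude",
                                      coh["incomplete"])


class TestAnalyzeSkeletonStats:
    def test_stats_fields_consistent(self):
        skel = np.zeros((10, 10, 10), bool)
        skel[2:8, 5, 5] = True
        stats = analyze_skeleton(skel, mask_voxels=1000, vessel_voxels=60)
        assert stats.n_segments == 1
        assert stats.vascular_volume_fraction == pytest.approx(0.06)
        assert stats.skeleton_voxels == 6
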