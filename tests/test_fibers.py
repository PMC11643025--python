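"""3D fiber morphometry: thresholding, labeling, sphericity filter, volumes."""

import numpy as np
import pytest
from skimage import measure

from epiquant.fibers import (
    FiberComponent,
    fiber_pipeline,
    filter_components,
    label_components,
    sphericity,
    threshold_stack,
    total_fiber_volume,
)
from epiquant.image import IntensityImage
from epiquant.synthetic import BLOB_LABEL, FIBER_LABEL, make_fiber_stack

VOX = dict(pixel_size_um=1.0, z_step_um=1.0)


def _ball(radius, pad=3):
    n = 2 * radius + 2 * pad
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestThreshold:
    def test_zero_threshold_keeps_everything(self):
        stack = IntensityImage(np.ones((4, 5, 6)), z_step_um=1.0)
        assert threshold_stack(stack, 0.0).all()

    def test_threshold_above_max_keeps_nothing(self):
        stack = IntensityImage(np.ones((4, 5, 6)), z_step_um=1.0)
        assert not threshold_stack(stack, 2.0).any()

    def test_bimodal_stack_recovers_object_voxels(self):
        stack, truth = make_fiber_stack(3, shape=(32, 64, 64), n_fibers=2, n_blobs=3,
                                        fiber_length_vox=40)
        fg = threshold_stack(stack, 100.0)
        np.testing.assert_array_equal(fg, truth.labels > 0)

    def test_raising_threshold_never_increases_foreground(self, rng):
        stack = IntensityImage(rng.random((10, 20, 20)) * 100, z_step_um=1.0)
        counts = [threshold_stack(stack, t).sum() for t in (10, 30, 50, 70, 90)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestLabelComponents:
    def test_single_voxel_component(self):
        stack = np.zeros((5, 5, 5), dtype=bool)
        stack[2, 2, 2] = True
        comps = label_components(stack, pixel_size_um=0.1, z_step_um=0.2)
        assert len(comps) == 1
        assert comps[0].voxel_count == 1
        assert comps[0].volume_um3 == pytest.approx(0.1 * 0.1 * 0.2)
        assert comps[0].sphericity <= 1.1

    def test_corner_touching_voxels_depend_on_connectivity(self):
        stack = np.zeros((4, 4, 4), dtype=bool)
        stack[1, 1, 1] = True
        stack[2, 2, 2] = True
        assert len(label_components(stack, connectivity=26, **VOX)) == 1
        assert len(label_components(stack, connectivity=6, **VOX)) == 2

    def test_ball_is_spherical_rod_is_not(self):
        ball = label_components(_ball(10), **VOX)[0]
        assert ball.sphericity >= 0.9
        rod = np.zeros((70, 9, 9), dtype=bool)
        rod[5:65, 3:6, 3:6] = True
        assert label_components(rod, **VOX)[0].sphericity < 0.7

    def test_face_counting_deflates_ball_sphericity(self):
        # documented bias of the voxel-face surface estimate
        mesh = label_components(_ball(7), **VOX)[0].sphericity
        faces = label_components(_ball(7), surface_method="faces", **VOX)[0].sphericity
        assert faces < mesh

    def test_ball_sphericity_calibration_across_radii(self):
        for r in (3, 5, 8, 10):
            psi = label_components(_ball(r), **VOX)[0].sphericity
            assert 0.85 <= psi <= 1.05

    def test_anisotropic_voxels_scale_volume(self):
        stack = np.zeros((6, 6, 6), dtype=bool)
        stack[2:4, 2:4, 2:4] = True
        comp = label_components(stack, pixel_size_um=0.065, z_step_um=0.2)[0]
        assert comp.volume_um3 == pytest.approx(8 * 0.065**2 * 0.2)


class TestFilter:
    def _comp(self, volume, psi):
        return FiberComponent(label=1, voxel_count=1, volume_um3=volume,
                              surface_area_um2=1.0, sphericity=psi, bbox=(0,) * 6)

    def test_large_spherical_object_retained(self):
        comps = [self._comp(volume=2.0, psi=0.95)]
        assert filter_components(comps, 0.5, 0.8) == comps

    def test_small_spherical_object_removed(self):
        ball = label_components(_ball(4), pixel_size_um=0.065, z_step_um=0.065)
        assert ball[0].volume_um3 < 0.5 and ball[0].sphericity > 0.8
        assert filter_components(ball) == []

    def test_small_thin_rod_retained(self):
        rod = np.zeros((40, 9, 9), dtype=bool)
        rod[4:36, 3:6, 3:6] = True
        comps = label_components(rod, pixel_size_um=0.065, z_step_um=0.065)
        assert comps[0].volume_um3 < 0.5 and comps[0].sphericity <= 0.8
        assert filter_components(comps) == comps

    def test_stricter_filters_never_increase_total_volume(self):
        stack, _ = make_fiber_stack(11, shape=(48, 96, 96), n_fibers=3, n_blobs=6,
                                    fiber_length_vox=50)
        _, base = fiber_pipeline(stack, 100.0, min_volume_um3=0.2)
        _, bigger_min = fiber_pipeline(stack, 100.0, min_volume_um3=1.0)
        _, lower_psi = fiber_pipeline(stack, 100.0, min_volume_um3=0.2,
                                      max_sphericity_for_small=0.5)
        assert bigger_min <= base
        assert lower_psi <= base


class TestVolumes:
    def test_empty_and_additive_totals(self):
        assert total_fiber_volume([]) == 0.0
        comps = [
            FiberComponent(1, 10, 10.0, 1.0, 0.5, (0,) * 6),
            FiberComponent(2, 15, 15.0, 1.0, 0.5, (0,) * 6),
        ]
        assert total_fiber_volume(comps) == pytest.approx(25.0)

    def test_volume_conservation_before_filtering(self):
        stack, _ = make_fiber_stack(5, shape=(48, 96, 96), n_fibers=3, n_blobs=5,
                                    fiber_length_vox=50)
        fg = threshold_stack(stack, 100.0)
        comps = label_components(fg, stack.pixel_size_um, stack.z_step_um)
        assert total_fiber_volume(comps) == pytest.approx(fg.sum() * stack.voxel_volume_um3())

    def test_axis_aligned_cylinder_volume_near_analytic(self):
        r, length = 3.0, 60
        yy, xx = np.mgrid[0:9, 0:9]
        disk = (yy - 4) ** 2 + (xx - 4) ** 2 <= r**2
        stack = np.zeros((70, 9, 9), dtype=bool)
        stack[5:5 + length] = disk
        comp = label_components(stack, **VOX)[0]
        assert comp.volume_um3 == pytest.approx(np.pi * r**2 * length, rel=0.10)


class TestRecovery:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_fiber_recall_and_blob_leakage_at_defaults(self, seed):
        stack, truth = make_fiber_stack(seed)
        kept, _ = fiber_pipeline(stack, 100.0)
        fg = threshold_stack(stack, 100.0)
        labels = measure.label(fg, connectivity=3)
        retained = np.isin(labels, [c.label for c in kept])
        fiber_voxels = truth.labels == FIBER_LABEL
        blob_voxels = truth.labels == BLOB_LABEL
        recall = (retained & fiber_voxels).sum() / fiber_voxels.sum()
        leakage = (retained & blob_voxels).sum() / blob_voxels.sum()
        assert recall >= 0.95
        assert leakage <= 0.05
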