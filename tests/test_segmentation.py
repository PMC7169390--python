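import math

import numpy as np
import pytest

from zeonco.io import VoxelStack
from zeonco.segmentation import (
    classify_primary,
    estimate_background,
    locate_eye,
    segment_larva,
    segment_tumor,
)
from zeonco.synthetic import SyntheticLarvaSpec, render_larva


def _stack(arr, voxel_size=(1.0, 1.0, 1.0)):
    return VoxelStack(np.asarray(arr, dtype=float), voxel_size)


class TestBackground:
    def test_constant_stack(self):
        assert estimate_background(_stack(np.full((4, 4, 4), 7.0))) == 7.0

    def test_all_zero(self):
        assert estimate_background(_stack(np.zeros((4, 4, 4)))) == 0.0

    def test_small_bright_blob_ignored(self):
        rng = np.random.default_rng(0)
        arr = 10.0 + rng.normal(0, 1.0, size=(20, 20, 20))
        arr[:2, :2, :2] = 500.0  # <1% of voxels
        arr = np.clip(arr, 0, None)
        assert abs(estimate_background(_stack(arr)) - 10.0) < 1.0


class TestSegmentTumor:
    def test_single_cube_fixed_threshold(self):
        arr = np.zeros((20, 20, 20))
        arr[5:15, 5:15, 5:15] = 100.0
        masses, thr = segment_tumor(
            _stack(arr), method="fixed", fixed_threshold=50, min_voxels=1
        )
        assert thr == 50
        assert len(masses) == 1
        assert masses[0].voxel_count == 1000
        assert masses[0].volume_um3 == 1000.0

    def test_two_separated_cubes_are_two_masses(self):
        arr = np.zeros((10, 10, 20))
        arr[2:5, 2:5, 2:5] = 100.0
        arr[2:5, 2:5, 10:13] = 100.0
        masses, _ = segment_tumor(
            _stack(arr), method="fixed", fixed_threshold=50, min_voxels=1
        )
        assert len(masses) == 2

    def test_diagonal_touch_is_one_mass_26conn(self):
        arr = np.zeros((6, 6, 6))
        arr[1, 1, 1] = 100.0
        arr[2, 2, 2] = 100.0  # corner contact only
        masses, _ = segment_tumor(
            _stack(arr), method="fixed", fixed_threshold=50, min_voxels=1
        )
        assert len(masses) == 1
        assert masses[0].voxel_count == 2

    def test_min_voxels_filters_speckles(self):
        arr = np.zeros((10, 10, 10))
        arr[2:6, 2:6, 2:6] = 100.0  # 64 voxels
        arr[8, 8, 8] = 100.0  # speckle
        masses, _ = segment_tumor(
            _stack(arr), method="fixed", fixed_threshold=50, min_voxels=30
        )
        assert len(masses) == 1

    def test_fixed_without_threshold_errors(self):
        with pytest.raises(ValueError, match="fixed_threshold"):
            segment_tumor(_stack(np.zeros((3, 3, 3))), method="fixed")

    def test_degenerate_threshold_warns_not_errors(self):
        arr = np.full((5, 5, 5), 10.0)
        arr[0, 0, 0] = 11.0
        with pytest.warns(UserWarning, match="background"):
            segment_tumor(_stack(arr), method="fixed", fixed_threshold=5, min_voxels=1)

    def test_otsu_on_noisy_ellipsoid_within_10pct_of_analytic(self):
        spec = SyntheticLarvaSpec(
            grid_shape=(40, 80, 160),
            voxel_size=(1.0, 1.0, 1.0),
            primary_center=(20.0, 40.0, 90.0),
            primary_semi_axes=(12.0, 15.0, 15.0),
            eye_center=(20.0, 40.0, 20.0),
            eye_radius=8.0,
            noise_sd=0.05 * 90.0,  # 5% of the background-to-foreground contrast
            seed=2,
        )
        stack = render_larva(spec, "tp1")
        seg = segment_larva(stack, eye_annotation_um=spec.eye_center, min_voxels=30)
        analytic = spec.true_volume_tp1
        assert abs(seg.primary.volume_um3 - analytic) / analytic < 0.10

    def test_volume_conservation(self):
        """Sum of mass volumes equals surviving supra-threshold voxels times
        the voxel volume, exactly."""
        rng = np.random.default_rng(3)
        arr = rng.choice([0.0, 100.0], p=[0.9, 0.1], size=(15, 15, 15))
        stack = _stack(arr, voxel_size=(2.0, 0.5, 0.5))
        masses, _ = segment_tumor(stack, method="fixed", fixed_threshold=50, min_voxels=5)
        from scipy import ndimage as ndi

        labels, _n = ndi.label(arr > 50, structure=np.ones((3, 3, 3)))
        counts = np.bincount(labels.ravel())[1:]
        surviving = int(counts[counts >= 5].sum())
        assert sum(m.voxel_count for m in masses) == surviving
        assert sum(m.volume_um3 for m in masses) == pytest.approx(
            surviving * 0.5, abs=1e-9
        )

    def test_intensity_shift_equivariance_fixed_mode(self):
        rng = np.random.default_rng(4)
        arr = np.clip(rng.normal(20, 5, size=(12, 12, 12)), 0, None)
        arr[3:7, 3:7, 3:7] = 100.0
        m1, _ = segment_tumor(_stack(arr), method="fixed", fixed_threshold=60, min_voxels=1)
        m2, _ = segment_tumor(
            _stack(arr + 25.0), method="fixed", fixed_threshold=85, min_voxels=1
        )
        assert [m.voxel_count for m in m1] == [m.voxel_count for m in m2]
        assert [m.centroid_um for m in m1] == [m.centroid_um for m in m2]

    def test_recovery_error_decreases_with_finer_voxels(self):
        """On noise-free renders the primary-volume error shrinks as voxel
        size shrinks."""
        errors = []
        for dv in (4.0, 1.0):
            spec = SyntheticLarvaSpec(
                grid_shape=(int(60 / dv), int(80 / dv), int(160 / dv)),
                voxel_size=(dv, dv, dv),
                primary_center=(30.0, 40.0, 90.0),
                primary_semi_axes=(11.0, 13.0, 13.0),
                eye_center=(30.0, 40.0, 20.0),
                eye_radius=8.0,
                noise_sd=0.0,
                seed=0,
            )
            seg = segment_larva(
                render_larva(spec, "tp1"),
                eye_annotation_um=spec.eye_center,
                method="fixed",
                fixed_threshold=55.0,
                min_voxels=1,
            )
            errors.append(
                abs(seg.primary.volume_um3 - spec.true_volume_tp1)
                / spec.true_volume_tp1
            )
        assert errors[1] < errors[0]

    def test_agrees_with_bruteforce_flood_fill_on_small_stacks(self):
        """Component labeling matches an independent BFS flood fill."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            arr = (rng.random((12, 12, 12)) < 0.15) * 100.0
            masses, _ = segment_tumor(
                _stack(arr), method="fixed", fixed_threshold=50, min_voxels=1
            )
            assert sorted(m.voxel_count for m in masses) == sorted(
                _flood_fill_sizes(arr > 50)
            )


def _flood_fill_sizes(mask):
    """Brute-force 26-connected component sizes via BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    shape = mask.shape
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack_ = [start]
        seen[start] = True
        size = 0
        while stack_:
            z, y, x = stack_.pop()
            size += 1
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if (
                    0 <= q[0] < shape[0]
                    and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2]
                    and mask[q]
                    and not seen[q]
                ):
                    seen[q] = True
                    stack_.append(q)
        sizes.append(size)
    return sizes


class TestClassifyPrimary:
    def _mass(self, mid, count, centroid):
        from zeonco.segmentation import SegmentedMass

        return SegmentedMass(mid, count, float(count), centroid, ((0, 1),) * 3)

    def test_largest_is_primary(self):
        masses = [
            self._mass(1, 1000, (0, 0, 0)),
            self._mass(2, 50, (0, 0, 50)),
            self._mass(3, 20, (0, 0, 90)),
        ]
        out = classify_primary(masses, (0, 0, 0))
        assert [m.is_primary for m in out] == [True, False, False]

    def test_tie_broken_by_injection_proximity(self):
        masses = [
            self._mass(1, 100, (0, 0, 80.0)),
            self._mass(2, 100, (0, 0, 30.0)),
        ]
        out = classify_primary(masses, injection_ref_um=(0, 0, 25.0))
        assert not out[0].is_primary and out[1].is_primary

    def test_single_mass_is_primary(self):
        out = classify_primary([self._mass(1, 10, (1, 1, 1))])
        assert out[0].is_primary

    def test_empty_in_empty_out(self):
        assert classify_primary([]) == []


class TestLocateEye:
    def test_annotation_passthrough(self):
        stack = _stack(np.zeros((20, 60, 60)))
        assert locate_eye(stack, annotation_um=(10, 50, 30)) == (10.0, 50.0, 30.0)

    def test_annotation_outside_grid_rejected(self):
        stack = _stack(np.zeros((20, 60, 60)))
        with pytest.raises(ValueError, match="outside"):
            locate_eye(stack, annotation_um=(10, 50, 300))

    def test_detects_synthetic_eye_within_2um(self):
        spec = SyntheticLarvaSpec(
            grid_shape=(40, 80, 160),
            voxel_size=(1.0, 1.0, 1.0),
            primary_center=(20.0, 40.0, 90.0),
            primary_semi_axes=(12.0, 12.0, 12.0),
            eye_center=(20.0, 40.0, 20.0),
            eye_radius=8.0,
            noise_sd=2.0,
            seed=1,
        )
        found = locate_eye(render_larva(spec, "tp1"))
        assert math.dist(found, spec.eye_center) < 2.0

    def test_blank_stack_instructs_manual_annotation(self):
        with pytest.raises(ValueError, match="annotation"):
            locate_eye(_stack(np.zeros((10, 20, 40))))
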