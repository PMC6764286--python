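"""3D detection, density and size quantification."""

import numpy as np
import pytest
from scipy import ndimage

from mgquant import synthetic as syn
from mgquant import stacks as st


def _otsu_separation(img):
    """Otsu class separability: between-class variance / total variance.

    The normalized form is scale-invariant, so background subtraction
    (which shrinks all intensities) cannot trivially lower it."""
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(img)
    m = img > thr
    p = m.mean()
    if p in (0.0, 1.0):
        return 0.0
    return p * (1 - p) * (img[m].mean() - img[~m].mean()) ** 2 / img.var()


def _two_ball_stack(sep_z_vox=8):
    """Two somata whose blurred intensities merge into one component but
    retain two maxima."""
    z = np.zeros((40, 60, 60))
    pitches = (1.5, 0.592, 0.592)
    syn._stamp_ball(z, np.array([17.0, 17.0, 27.0]), 4.0, 100.0, pitches)
    syn._stamp_ball(z, np.array([17.0, 17.0, 27.0 + sep_z_vox]), 4.0, 100.0, pitches)
    z = ndimage.gaussian_filter(z, [0.5 / p for p in pitches])
    return st.ImageStack3D(z)


class TestPreprocess:
    def test_zero_scales_is_identity(self, small_stack_spec):
        img, _ = syn.generate_stack(small_stack_spec, 0)
        stack = st.ImageStack3D(img)
        out = st.preprocess_stack(stack, smoothing_sigma=0.0, background_radius=0.0)
        assert np.array_equal(out.voxels, img)
        assert out.voxel_xy == stack.voxel_xy and out.voxel_z == stack.voxel_z

    def test_constant_stack_background_subtracts_to_zero(self):
        stack = st.ImageStack3D(np.full((8, 16, 16), 42.0))
        out = st.preprocess_stack(stack, smoothing_sigma=0.0, background_radius=5.0)
        assert np.allclose(out.voxels, 0.0)

    def test_nonfinite_rejected(self):
        bad = np.zeros((4, 8, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            st.preprocess_stack(st.ImageStack3D(bad))

    def test_separation_non_decreasing(self):
        spec = syn.StackSpec(shape_xyz=(128, 128, 20), n_cells=5, min_separation=25.0)
        for seed in range(10):
            img, _ = syn.generate_stack(spec, seed)
            stack = st.ImageStack3D(img)
            pre = st.preprocess_stack(stack)
            assert _otsu_separation(pre.voxels) >= _otsu_separation(
                img.astype(np.float64)
            )


class TestDetect:
    def test_blank_stack_empty(self):
        spec = syn.StackSpec(shape_xyz=(96, 96, 16), n_cells=0)
        img, _ = syn.generate_stack(spec, 4)
        pre = st.preprocess_stack(st.ImageStack3D(img))
        cells, labels = st.detect_cells_3d(pre)
        assert cells == []
        assert labels.max() == 0

    def test_constant_stack_zero_cells(self):
        cells, _ = st.detect_cells_3d(st.ImageStack3D(np.full((6, 10, 10), 7.0)))
        assert cells == []

    def test_empty_stack_invalid(self):
        with pytest.raises(ValueError):
            st.ImageStack3D(np.zeros((0, 4, 4)))

    def test_recovers_separated_cells_with_matched_centroids(self):
        spec = syn.StackSpec(shape_xyz=(256, 256, 30), n_cells=12, min_separation=30.0)
        img, truth = syn.generate_stack(spec, 9)
        pre = st.preprocess_stack(st.ImageStack3D(img))
        cells, _ = st.detect_cells_3d(pre)
        assert len(cells) == 12
        tc = np.array([t.centroid for t in truth])
        for c in cells:
            d = np.linalg.norm(tc - np.asarray(c.centroid), axis=1)
            nearest = d.argmin()
            assert d[nearest] <= truth[nearest].soma_radius

    def test_touching_somata_split_by_watershed(self):
        stack = _two_ball_stack()
        on, _ = st.detect_cells_3d(stack, split_touching=True)
        off, _ = st.detect_cells_3d(stack, split_touching=False)
        assert len(off) == 1
        assert len(on) == 2

    def test_labels_disjoint_and_sizes_bounded(self):
        spec = syn.StackSpec(shape_xyz=(192, 192, 24), n_cells=6, min_separation=28.0)
        img, _ = syn.generate_stack(spec, 2)
        pre = st.preprocess_stack(st.ImageStack3D(img))
        cells, labels = st.detect_cells_3d(pre)
        # disjoint by construction of a label image; counts must match
        assert sum(c.n_voxels for c in cells) == (labels > 0).sum()
        # sum of cell sizes cannot exceed total thresholded foreground
        thr = st.otsu_with_floor(pre.voxels)
        fg_vol = (pre.voxels > thr).sum() * pre.voxel_volume_um3
        assert sum(c.size for c in cells) <= fg_vol + 1e-9


class TestDensity:
    def test_volume_and_density_match_hand_arithmetic(self):
        stack = st.ImageStack3D(np.zeros((100, 1024, 1024), dtype=np.uint8))
        rec = st.compute_density(100, stack)
        vol_um3 = (1024 * 0.592) ** 2 * (100 * 1.5)
        assert rec.volume_mm3 == pytest.approx(vol_um3 * 1e-9, rel=1e-12)
        assert rec.density == pytest.approx(100 / (vol_um3 * 1e-9), rel=1e-12)
        assert rec.density == pytest.approx(1814.3, abs=0.5)

    def test_density_linear_in_count(self):
        stack = st.ImageStack3D(np.zeros((10, 64, 64)))
        assert st.compute_density(0, stack).density == 0.0
        d1 = st.compute_density(7, stack).density
        d2 = st.compute_density(14, stack).density
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_density_2d_matches_hand_arithmetic(self):
        rec = st.compute_density_2d(200, (1024, 1024), 2.3649)
        area_um2 = (1024 * 2.3649) ** 2
        assert rec.area_mm2 == pytest.approx(area_um2 * 1e-6, rel=1e-12)
        assert rec.density == pytest.approx(200 / (area_um2 * 1e-6), rel=1e-12)
        assert rec.density == pytest.approx(34.1, abs=0.1)

    def test_density_2d_quadruples_when_mpp_halves(self):
        d1 = st.compute_density_2d(50, (512, 512), 1.0).density
        d2 = st.compute_density_2d(50, (512, 512), 0.5).density
        assert d2 == pytest.approx(4 * d1, rel=1e-12)

    def test_invalid_geometry_errors(self):
        with pytest.raises(ValueError):
            st.compute_density_2d(1, (0, 512), 1.0)
        with pytest.raises(ValueError):
            st.compute_density(-1, st.ImageStack3D(np.zeros((2, 2, 2))))


class TestCellSize:
    def test_single_voxel_volume(self):
        stack = st.ImageStack3D(np.zeros((2, 2, 2)), voxel_xy=0.592, voxel_z=1.5)
        cell = st.DetectedCell(1, (0, 0, 0), n_voxels=1, size=0.0)
        assert st.measure_cell_size(cell, stack) == pytest.approx(
            0.592**2 * 1.5, rel=1e-12
        )

    @staticmethod
    def _rasterized_ball_voxels(radius, pitch):
        n = int(np.ceil((radius + 2) / pitch))
        ax = (np.arange(-n, n + 1) + 0.5) * pitch
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        return int((zz**2 + yy**2 + xx**2 <= radius**2).sum())

    def test_ball_volume_converges_to_analytic(self):
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        errors = []
        for pitch in (2.0, 1.0, 0.5):
            n_vox = self._rasterized_ball_voxels(10.0, pitch)
            stack = st.ImageStack3D(np.zeros((2, 2, 2)), voxel_xy=pitch, voxel_z=pitch)
            cell = st.DetectedCell(1, (0, 0, 0), n_voxels=n_vox, size=0.0)
            vol = st.measure_cell_size(cell, stack)
            errors.append(abs(vol - analytic) / analytic)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.05

    def test_disjoint_union_additive(self):
        stack = st.ImageStack3D(np.zeros((2, 2, 2)), voxel_xy=1.0, voxel_z=2.0)
        a = st.DetectedCell(1, (0, 0, 0), n_voxels=10, size=0.0)
        b = st.DetectedCell(2, (0, 0, 0), n_voxels=25, size=0.0)
        union = st.DetectedCell(3, (0, 0, 0), n_voxels=35, size=0.0)
        assert st.measure_cell_size(union, stack) == pytest.approx(
            st.measure_cell_size(a, stack) + st.measure_cell_size(b, stack)
        )

    def test_empty_voxel_set_errors(self):
        stack = st.ImageStack3D(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            st.measure_cell_size(st.DetectedCell(1, (0, 0, 0), 0, 0.0), stack)


class TestPooledDensity:
    def test_pooled_vs_mean_of_stacks(self):
        s1 = st.ImageStack3D(np.zeros((10, 64, 64)))
        s2 = st.ImageStack3D(np.zeros((20, 64, 64)))
        r1 = st.compute_density(10, s1)
        r2 = st.compute_density(40, s2)
        pooled = st.pooled_density([r1, r2])
        mean = st.pooled_density([r1, r2], method="mean")
        assert pooled == pytest.approx(50 / (s1.volume_mm3 + s2.volume_mm3))
        assert mean == pytest.approx((r1.density + r2.density) / 2)
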