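"""The segmentation chain: gradients, angles, classification, labelling.

Brute-force per-pixel loops serve as oracles for the vectorised difference
operators, and an independent flood-fill labelling (scipy.ndimage) checks the
two-pass union-find labelling on random masks.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from autolia import DepthMap, SegParams, default_camera
from autolia import depthseg as ds
from autolia.errors import InvalidInputError

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def flat_depth(h=20, w=24, z=2.0):
    return DepthMap.from_array(np.full((h, w), z))


class TestGradients:
    def test_constant_plane_has_zero_gradients(self):
        g = ds.depth_to_gradient(flat_depth())
        assert np.allclose(g.down[g.valid_down], 0)
        assert np.allclose(g.right[g.valid_right], 0)

    def test_linear_ramp_along_columns(self):
        u = np.arange(24)[None, :] * np.ones((20, 1))
        depth = DepthMap.from_array(2.0 + 0.01 * u)
        g = ds.depth_to_gradient(depth)
        assert np.allclose(g.right[g.valid_right], 0.01)
        assert np.allclose(g.down[g.valid_down], 0.0)

    def test_matches_naive_double_loop(self, rng):
        z = rng.uniform(1, 3, (12, 15))
        z[rng.random((12, 15)) < 0.1] = np.nan  # some invalid pixels
        depth = DepthMap.from_array(z)
        g = ds.depth_to_gradient(depth)
        for r in range(12):
            for c in range(15):
                if r + 1 < 12 and depth.valid_mask[r, c] and depth.valid_mask[r + 1, c]:
                    assert g.down[r, c] == pytest.approx(z[r + 1, c] - z[r, c])
                else:
                    assert not g.valid_down[r, c]
                if c + 1 < 15 and depth.valid_mask[r, c] and depth.valid_mask[r, c + 1]:
                    assert g.right[r, c] == pytest.approx(z[r, c + 1] - z[r, c])
                else:
                    assert not g.valid_right[r, c]

    def test_too_small_map_rejected(self):
        with pytest.raises(InvalidInputError):
            ds.depth_to_gradient(DepthMap.from_array(np.full((1, 5), 2.0)))


class TestAngles:
    def test_zero_gradient_gives_zero_angle(self, small_cam):
        depth = flat_depth()
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        assert np.allclose(ang.down[ang.valid_down], 0)
        assert np.allclose(ang.right[ang.valid_right], 0)

    def test_gradient_equal_to_footprint_gives_45_degrees(self, small_cam):
        # z(u+1) - z(u) == z / focal -> exact 45 deg (use exponential ramp so
        # the footprint grows with z consistently at one pixel: check at col 0)
        z0 = 2.0
        z = np.full((8, 8), z0)
        z[:, 1] = z0 + z0 / small_cam.focal_px
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        assert ang.right[0, 0] == pytest.approx(45.0)

    def test_planar_patch_recovers_slope_near_axis(self, small_cam):
        """A plane sloped along rows reads back arctan(slope) away from borders."""
        f = small_cam.focal_px
        slope = 0.3  # dz per metre of in-plane offset
        # plane z = z0 / (1 - slope * y'), y' = (v - cy)/f: constant local angle
        v = np.arange(24)[:, None] * np.ones((1, 32))
        yprime = (v - small_cam.cy) / f
        z = 2.0 / (1 - slope * yprime)
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        # near the principal row the footprint approximation is exact
        mid = int(small_cam.cy)
        assert ang.down[mid, 16] == pytest.approx(np.degrees(np.arctan(slope)), abs=0.1)


class TestAngleDifference:
    def test_planar_patch_zero_difference(self, small_cam):
        v = np.arange(24)[:, None] * np.ones((1, 32))
        z = 2.0 + 0.004 * v
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        diff = ds.angle_difference(ang)
        assert np.abs(diff.down[diff.valid_down]).max() < 0.5

    def test_two_planes_crease_localised(self, small_cam):
        """Two planes meeting at a crease: differences concentrate at the crease."""
        h, w = 24, 32
        v = np.arange(h)[:, None] * np.ones((1, w))
        z = np.where(v < 12, 2.0, 2.0 + 0.02 * (v - 12))  # flat then sloped
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        diff = ds.angle_difference(ang)
        big = np.abs(diff.down) > 10
        big &= diff.valid_down
        rows = np.nonzero(big.any(axis=1))[0]
        assert len(rows) > 0 and set(rows) <= {10, 11, 12}

    def test_matches_naive_loop(self, rng, small_cam):
        z = rng.uniform(1, 3, (10, 12))
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        diff = ds.angle_difference(ang)
        for r in range(10):
            for c in range(12):
                if diff.valid_down[r, c]:
                    assert diff.down[r, c] == pytest.approx(ang.down[r + 1, c] - ang.down[r, c])
                if diff.valid_right[r, c]:
                    assert diff.right[r, c] == pytest.approx(ang.right[r, c + 1] - ang.right[r, c])


def _classify(depth: DepthMap, cam, params: SegParams) -> ds.PixelClassMap:
    ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, cam)
    return ds.classify_pixels(ds.angle_difference(ang), params, angles=ang, depth=depth, cam=cam)


class TestClassification:
    def test_flat_map_all_surface(self, small_cam):
        for seg_th in (1.0, 0.5, 1 / 80):
            classes = _classify(flat_depth(), small_cam, SegParams(seg_th=seg_th))
            assert (classes.labels == ds.SURFACE).all()

    def test_step_discontinuity_yields_edge_band(self, small_cam):
        z = np.full((20, 24), 2.0)
        z[10:, :] = 1.0  # big step toward the camera
        classes = _classify(DepthMap.from_array(z), small_cam, SegParams(n_th=0))
        labels = classes.labels
        edge_rows = np.nonzero((labels == ds.EDGE).any(axis=1))[0]
        assert len(edge_rows) > 0 and set(edge_rows) <= {8, 9, 10}
        # away from the step everything is surface
        assert (labels[:8] == ds.SURFACE).all() and (labels[12:] == ds.SURFACE).all()
        # the step survives at n_th=2 too: the bridging chord is far too steep
        classes2 = _classify(DepthMap.from_array(z), small_cam, SegParams(n_th=2))
        assert (classes2.labels == ds.EDGE).any()

    def test_single_pixel_spike_healed_only_with_jump_pixels(self, small_cam):
        z = np.full((20, 24), 2.0)
        z[9, 11] = 4.0  # isolated mismatch outlier
        spike = DepthMap.from_array(z)
        healed = _classify(spike, small_cam, SegParams(n_th=2))
        assert (healed.labels == ds.SURFACE).all()
        kept = _classify(spike, small_cam, SegParams(n_th=0))
        assert (kept.labels == ds.EDGE).any()

    def test_threshold_monotonicity_before_healing(self, rng, small_cam):
        """Decreasing seg_th never decreases the number of raw edge flags."""
        z = rng.uniform(1.8, 2.2, (20, 24))
        depth = DepthMap.from_array(z)
        ang = ds.gradient_to_angle(ds.depth_to_gradient(depth), depth, small_cam)
        diff = ds.angle_difference(ang)
        counts = []
        for seg_th in (1.0, 0.5, 0.25, 0.1, 1 / 80):
            classes = ds.classify_pixels(diff, SegParams(seg_th=seg_th, n_th=0))
            counts.append(int((classes.labels == ds.EDGE).sum()))
        assert counts == sorted(counts)

    def test_invalid_pixels_propagate(self, small_cam):
        z = np.full((20, 24), 2.0)
        z[5, 5] = np.nan
        classes = _classify(DepthMap.from_array(z), small_cam, SegParams())
        assert classes.labels[5, 5] == ds.INVALID
        assert (classes.labels == ds.INVALID).sum() == 1


def _as_classmap(surface: np.ndarray) -> ds.PixelClassMap:
    labels = np.where(surface, ds.SURFACE, ds.EDGE).astype(np.uint8)
    return ds.PixelClassMap(labels)


class TestLabelling:
    def test_all_surface_single_region(self):
        table = ds.label_regions(_as_classmap(np.ones((10, 12), dtype=bool)))
        assert len(table) == 1
        assert table.table.area_px.iloc[0] == 120

    def test_two_blobs_separated_by_edge_line(self):
        surface = np.ones((11, 12), dtype=bool)
        surface[5, :] = False
        table = ds.label_regions(_as_classmap(surface))
        assert len(table) == 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_flood_fill_on_random_masks(self, seed):
        """Two-pass labelling partitions exactly like an independent flood fill."""
        rng = np.random.default_rng(seed)
        surface = rng.random((18, 22)) < rng.uniform(0.3, 0.8)
        mine = ds.label_regions(_as_classmap(surface)).label_map
        ref, n_ref = ndi.label(surface, structure=FOUR_CONN)
        assert mine.max() == n_ref
        assert ((mine > 0) == (ref > 0)).all()
        # identical partition up to label permutation
        pair = {}
        for a, b in zip(mine[surface], ref[surface]):
            assert pair.setdefault(a, b) == b

    def test_partition_property(self, rng):
        surface = rng.random((30, 30)) < 0.6
        table = ds.label_regions(_as_classmap(surface))
        assert (table.label_map > 0).sum() == surface.sum()
        assert table.table.area_px.sum() == surface.sum()


class TestFiltering:
    def test_specks_and_background_removed(self):
        surface = np.zeros((50, 60), dtype=bool)
        surface[2:22, 2:12] = True  # 200 px
        surface[2:22, 20:30] = True
        surface[30:45, 35:50] = True  # 225 px
        surface[48, 58] = True  # speck
        full = np.ones((50, 60), dtype=bool)
        full[surface] = True
        # background occupying everything else (big region)
        labels = ds.label_regions(_as_classmap(np.ones((50, 60), dtype=bool)))
        # build the scene class map: edges around blobs
        cm = np.full((50, 60), ds.SURFACE, dtype=np.uint8)
        cm[1, :] = ds.EDGE  # fence the top so blobs and bg are distinct
        cm[:, [1, 13, 19, 31, 34, 51]] = ds.EDGE
        cm[[23, 29, 46], :] = ds.EDGE
        table = ds.label_regions(ds.PixelClassMap(cm))
        filtered = ds.filter_regions(table, SegParams(min_area_frac=0.01, max_area_frac=0.5))
        sizes = sorted(filtered.table.area_px)
        assert all(0.01 * 3000 <= s <= 0.5 * 3000 for s in sizes)

    def test_identity_bounds_keep_everything(self, rng):
        surface = rng.random((20, 20)) < 0.5
        table = ds.label_regions(_as_classmap(surface))
        kept = ds.filter_regions(table, SegParams(min_area_frac=0.0, max_area_frac=1.0))
        assert len(kept) == len(table)
        assert kept.table.area_px.sum() == table.table.area_px.sum()

    def test_no_region_in_bounds_gives_empty_table(self):
        surface = np.zeros((20, 20), dtype=bool)
        surface[0, 0] = True
        table = ds.label_regions(_as_classmap(surface))
        filtered = ds.filter_regions(table, SegParams(min_area_frac=0.1, max_area_frac=0.5))
        assert len(filtered) == 0
        assert (filtered.label_map == 0).all()

    def test_relabelled_by_decreasing_size(self):
        surface = np.zeros((20, 30), dtype=bool)
        surface[1:4, 1:4] = True  # 9 px
        surface[6:16, 6:16] = True  # 100 px
        surface[18:20, 20:29] = True  # 18 px
        table = ds.label_regions(_as_classmap(surface))
        filtered = ds.filter_regions(table, SegParams(min_area_frac=0.0, max_area_frac=1.0))
        areas = list(filtered.table.area_px)
        assert areas == sorted(areas, reverse=True)
        assert filtered.table.label.tolist() == [1, 2, 3]


class TestRecognitionAndNoise:
    def test_disjoint_planar_leaves_recovered_at_recommended_thresholds(self):
        """k disjoint leaves at seg_th=0.5, n_th=2 give exactly k regions."""
        from autolia import render_depth, standard_scene

        for k in (2, 3):
            depth, gt = render_depth(standard_scene(32.5, 40.0, n_leaves=k))
            table = ds.segment(depth, default_camera(), SegParams())
            assert len(table) == k

    def test_salt_runs_do_not_change_filtered_region_count(self):
        """Mismatch runs no wider than n_th leave the region count unchanged."""
        from autolia import add_streaks, render_depth, standard_scene

        depth, gt = render_depth(standard_scene(32.5, 40.0, n_leaves=2))
        cam = default_camera()
        base = len(ds.segment(depth, cam, SegParams(n_th=2)))
        streaks = []
        for leaf in gt.leaves:
            rows, cols = np.nonzero(leaf.mask)
            rmid = int(rows.mean())
            sel = cols[rows == rmid]
            streaks.append((rmid, int(sel.min()), int(sel.max()) + 1))
        noisy = add_streaks(depth, streaks)
        assert len(ds.segment(noisy, cam, SegParams(n_th=2))) == base


class TestDenoise:
    def test_median_removes_isolated_outliers(self):
        z = np.full((20, 20), 2.0)
        z[7, 9] = 4.0
        out = ds.denoise_depth(DepthMap.from_array(z), median_radius=1, gaussian_sigma=0.0)
        assert np.allclose(out.values, 2.0)

    def test_invalid_mask_preserved(self):
        z = np.full((20, 20), 2.0)
        z[3, 3] = np.nan
        out = ds.denoise_depth(DepthMap.from_array(z))
        assert out.invalid_mask[3, 3]
        assert out.invalid_mask.sum() == 1
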