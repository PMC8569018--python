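"""Morphometry descriptors against analytic shapes and exhaustive oracles."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import kurtosis, skew, spearmanr

from embryopt.core import MultichannelVolume, Volume
from embryopt.morphometry import (DEFAULT_DESCRIPTOR_NAMES, Landmarks, ap_index,
                                  compute_descriptor_vector, compute_skeleton,
                                  detect_landmarks, geodesic_distance_map,
                                  intensity_stats, principal_axis_lengths,
                                  skeleton_surface_stats, solidity, tortuosity)
from embryopt.phantom import PhantomSpec, make_embryo_phantom
from embryopt.segmentation import EmbryoMask

from conftest import make_ball, make_cylinder, make_ellipsoid


class TestLandmarks:
    def test_single_voxel_argmax(self, small_phantom):
        _, truth = small_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), 1.0)
        chan = np.zeros(truth.mask.shape)
        p = tuple(np.round(truth.centerline[len(truth.centerline) // 2]).astype(int))
        chan[p] = 5.0
        vol = Volume(chan, voxel_size=1.0)
        lm = detect_landmarks(vol, vol, mask)
        np.testing.assert_array_equal(lm.anterior, p)

    def test_phantom_markers_near_truth(self, default_phantom):
        vol, truth = default_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), mask)
        assert np.linalg.norm(lm.anterior - truth.anterior_point) <= 2.0
        assert np.linalg.norm(lm.posterior - truth.posterior_point) <= 2.0

    def test_tie_breaks_to_lowest_linear_index(self):
        mask_arr = np.zeros((6, 6, 6), dtype=bool)
        mask_arr[1:5, 1:5, 1:5] = True
        mask = EmbryoMask(mask_arr, 1, int(mask_arr.sum()), 1.0)
        chan = np.zeros((6, 6, 6))
        chan[2, 3, 1] = chan[4, 1, 2] = 9.0  # equal maxima
        # brute-force scan in (z, y, x) order
        best = min(p for p in np.ndindex(chan.shape) if chan[p] == 9.0)
        lm = detect_landmarks(Volume(chan, voxel_size=1.0),
                              Volume(chan, voxel_size=1.0), mask)
        np.testing.assert_array_equal(lm.anterior, best)

    def test_empty_channel_errors(self):
        mask_arr = np.zeros((6, 6, 6), dtype=bool)
        mask_arr[2:4, 2:4, 2:4] = True
        mask = EmbryoMask(mask_arr, 1, int(mask_arr.sum()), 1.0)
        zero = Volume(np.zeros((6, 6, 6)), voxel_size=1.0)
        with pytest.raises(ValueError, match="landmark channel empty"):
            detect_landmarks(zero, zero, mask)


class TestSkeleton:
    def test_straight_cylinder_path(self):
        # the centerline is axial; it anchors at the medial depth margin,
        # so it stops about one radius short of each flat end cap
        mask = make_cylinder(radius=6, length=100)
        ends = Landmarks(np.array([10.0, 10.0, 4.0]), np.array([10.0, 10.0, 107.0]))
        sk = compute_skeleton(mask, ends)
        assert sk.path_length == pytest.approx(100.0, rel=0.10)
        assert tortuosity(sk) == pytest.approx(1.0, abs=0.02)
        # the path is the straight axis itself
        assert np.ptp(sk.path[:, 0]) == 0 and np.ptp(sk.path[:, 1]) == 0

    def test_curved_phantom_path_near_true_centerline(self, default_phantom):
        vol, truth = default_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        lm = Landmarks(truth.anterior_point, truth.posterior_point)
        sk = compute_skeleton(mask, lm)
        dev = cKDTree(truth.centerline).query(sk.path)[0]
        assert dev.mean() <= 2.0

    def test_ball_collapses_centrally(self):
        mask = make_ball(radius=15)
        lm = Landmarks(np.array([19.0, 19.0, 2.0]), np.array([19.0, 19.0, 36.0]))
        sk = compute_skeleton(mask, lm)
        assert sk.path_length <= 15.0

    def test_path_is_26_connected(self, default_phantom):
        vol, truth = default_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        sk = compute_skeleton(mask, Landmarks(truth.anterior_point,
                                              truth.posterior_point))
        steps = np.abs(np.diff(sk.path, axis=0))
        assert steps.max() <= 1.0


class TestPrincipalAxes:
    def test_ball_isotropic(self):
        L1, _, L3 = principal_axis_lengths(make_ball(radius=12))
        assert L3 / L1 == pytest.approx(1.0, abs=0.02)

    def test_ellipsoid_ratios_analytic(self):
        L1, L2, L3 = principal_axis_lengths(make_ellipsoid(40, 20, 10))
        assert L2 / L1 == pytest.approx(0.50, abs=0.03)
        assert L3 / L1 == pytest.approx(0.25, abs=0.03)

    def test_rotation_invariance(self):
        a = principal_axis_lengths(make_ellipsoid(40, 20, 10, order=(0, 1, 2)))
        b = principal_axis_lengths(make_ellipsoid(40, 20, 10, order=(1, 0, 2)))
        np.testing.assert_allclose(a, b, rtol=0.02)

    def test_degenerate_mask_errors(self):
        tiny = np.zeros((4, 4, 4), dtype=bool)
        tiny[1, 1, 1] = True
        with pytest.raises(ValueError, match="degenerate"):
            principal_axis_lengths(EmbryoMask(tiny, 1, 1, 1.0))


class TestSolidity:
    def test_convex_ellipsoid_near_one(self):
        assert solidity(make_ellipsoid(20, 12, 8)) >= 0.97

    def test_l_shape_matches_delaunay_hull_oracle(self):
        """Hull voxel count cross-checked by exhaustive Delaunay membership."""
        mask_arr = np.zeros((26, 26, 26), dtype=bool)
        mask_arr[3:23, 3:11, 3:11] = True
        mask_arr[3:11, 3:23, 3:11] = True
        mask = EmbryoMask(mask_arr, 1, int(mask_arr.sum()), 1.0)
        s = solidity(mask)
        hull = Delaunay(np.argwhere(mask_arr))
        centers = np.array(list(np.ndindex(mask_arr.shape)))
        hull_count = int((hull.find_simplex(centers) >= 0).sum())
        assert s == pytest.approx(mask_arr.sum() / hull_count, rel=0.02)

    def test_notch_decreases_solidity(self):
        mask = make_ellipsoid(18, 12, 10)
        s_convex = solidity(mask)
        notched = mask.mask.copy()
        c = np.asarray(notched.shape) // 2
        notched[c[0] - 3:c[0] + 3, c[1] - 12:c[1] + 2, c[2] - 3:c[2] + 3] = False
        m2 = EmbryoMask(notched, 1, int(notched.sum()), 1.0)
        assert solidity(m2) < s_convex


class TestTortuosity:
    def test_semicircular_arc(self):
        spec = PhantomSpec(target_tortuosity=float(np.pi / 2),
                           volume_shape=(48, 104, 104), radius_profile=26.0,
                           axis_fraction=0.62)
        vol, truth = make_embryo_phantom(spec)
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        sk = compute_skeleton(mask, Landmarks(truth.anterior_point,
                                              truth.posterior_point))
        assert tortuosity(sk, vol.voxel_size) == pytest.approx(np.pi / 2, abs=0.05)

    def test_always_at_least_one(self, cohort_descriptors):
        table, _, _ = cohort_descriptors
        assert (table["tortuosity"] >= 1.0).all()

    def test_cohort_parameter_recovery(self, cohort_descriptors):
        """Measured tortuosity ranks the requested severity across 20 phantoms."""
        table, _, truths = cohort_descriptors
        requested = [t.true_tortuosity for t in truths]
        rho = spearmanr(requested, table["tortuosity"]).statistic
        assert rho >= 0.95


class TestSkeletonSurfaceStats:
    def test_uniform_cylinder(self):
        mask = make_cylinder(radius=10, length=80, voxel_size=2.0)
        lm = Landmarks(np.array([14.0, 14.0, 4.0]), np.array([14.0, 14.0, 87.0]))
        sk = compute_skeleton(mask, lm)
        mean, variation, _, _ = skeleton_surface_stats(mask, sk)
        assert mean == pytest.approx(10.0 * 2.0, rel=0.1)
        assert variation <= 0.05

    def test_distances_match_exhaustive_search(self):
        mask = make_cylinder(radius=4, length=14)
        lm = Landmarks(np.array([8.0, 8.0, 4.0]), np.array([8.0, 8.0, 21.0]))
        sk = compute_skeleton(mask, lm)
        from embryopt.morphometry import surface_voxels
        surf = np.argwhere(surface_voxels(mask.mask))
        edt = ndimage.distance_transform_edt(~surface_voxels(mask.mask))
        for p in sk.path.astype(int):
            brute = np.sqrt(((surf - p) ** 2).sum(axis=1)).min()
            assert edt[tuple(p)] == pytest.approx(brute, abs=1e-9)

    @staticmethod
    def _ramp_tube():
        """Straight tube whose radius ramps 32.5 -> 97.5 µm (5 -> 15 voxels)."""
        vs = 6.5
        pts = [(30 * vs, 30 * vs, 20 * vs), (30 * vs, 30 * vs, 100 * vs)]
        spec = PhantomSpec(centerline_control_points=pts,
                           radius_profile=lambda s: 32.5 + 65.0 * s,
                           volume_shape=(60, 60, 120), voxel_size=vs)
        return make_embryo_phantom(spec)

    def test_ramp_tube_distances_track_true_radii(self):
        vol, truth = self._ramp_tube()
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        sk = compute_skeleton(mask, Landmarks(truth.anterior_point,
                                              truth.posterior_point))
        from embryopt.morphometry import surface_voxels
        edt = ndimage.distance_transform_edt(~surface_voxels(mask.mask))
        d = np.array([edt[tuple(p)] for p in sk.path.astype(int)])
        # local radius at each path voxel from the generator's radius ramp
        t0, t1 = truth.centerline[0], truth.centerline[-1]
        s = (sk.path[:, 2] - t0[2]) / (t1[2] - t0[2])
        true_r = (32.5 + 65.0 * np.clip(s, 0, 1)) / vol.voxel_size
        inner = slice(15, -15)  # away from cap-dominated ends
        assert np.abs(d[inner] - true_r[inner]).max() <= 1.5

    def test_moments_match_direct_formulas(self):
        vol, truth = self._ramp_tube()
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        sk = compute_skeleton(mask, Landmarks(truth.anterior_point,
                                              truth.posterior_point))
        from embryopt.morphometry import surface_voxels
        edt = ndimage.distance_transform_edt(~surface_voxels(mask.mask))
        d = np.array([edt[tuple(p)] for p in sk.path.astype(int)])
        # replicate the documented end-trim rule, then the textbook moments
        steps = np.linalg.norm(np.diff(sk.path, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(steps)])
        keep = np.minimum(arclen, arclen[-1] - arclen) >= d
        d = d[keep] * vol.voxel_size
        mean, variation, skw, kur = skeleton_surface_stats(mask, sk)
        assert mean == pytest.approx(d.mean())
        assert variation == pytest.approx(d.std(ddof=1) / d.mean())
        assert skw == pytest.approx(skew(d, bias=False))
        assert kur == pytest.approx(kurtosis(d, fisher=True, bias=False))


class TestAPIndex:
    def _path_mask(self, n=20):
        arr = np.zeros((3, 3, n + 2), dtype=bool)
        arr[1, 1, 1:n + 1] = True
        return EmbryoMask(arr, 1, n, 1.0)

    def test_coincident_seeds_give_one(self):
        mask = self._path_mask()
        lm = Landmarks(np.array([1.0, 1.0, 5.0]), np.array([1.0, 1.0, 5.0]))
        assert ap_index(mask, lm) == pytest.approx(1.0)

    def test_straight_path_gives_minus_one(self):
        mask = self._path_mask()
        lm = Landmarks(np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 20.0]))
        assert ap_index(mask, lm) == pytest.approx(-1.0, abs=0.01)

    def test_distance_map_matches_dijkstra_oracle(self):
        """Geodesic map on a path graph equals hand-rolled BFS distances."""
        n = 20
        mask = self._path_mask(n)
        dmap = geodesic_distance_map(mask.mask, np.array([1.0, 1.0, 1.0]))
        for x in range(1, n + 1):
            assert dmap[1, 1, x] == pytest.approx(float(x - 1))

    def test_geodesic_exceeds_euclidean_on_bent_body(self, default_phantom):
        vol, truth = default_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), 1.0)
        d = geodesic_distance_map(mask.mask, truth.anterior_point)
        chord = np.linalg.norm(truth.posterior_point - truth.anterior_point)
        p = tuple(np.round(truth.posterior_point).astype(int))
        assert d[p] >= chord - 1e-6

    def test_disconnected_mask_errors(self):
        arr = np.zeros((3, 3, 10), dtype=bool)
        arr[1, 1, 1:3] = True
        arr[1, 1, 6:8] = True
        with pytest.raises(ValueError, match="disconnected"):
            geodesic_distance_map(arr, np.array([1.0, 1.0, 1.0]))


class TestIntensityStats:
    def test_min_subtraction_forced_example(self):
        mask_arr = np.zeros((1, 1, 3), dtype=bool)
        mask_arr[0, 0, :] = True
        vol = Volume(np.array([[[10.0, 12.0, 20.0]]]), voxel_size=1.0)
        mean, _, _, _ = intensity_stats(vol, EmbryoMask(mask_arr, 1, 3, 1.0))
        assert mean == pytest.approx(4.0)

    def test_moments_match_hand_formulas(self):
        vals = np.array([3.0, 7, 1, 9, 4, 4, 6, 2, 8, 5])
        vol = Volume(vals.reshape(1, 1, -1), voxel_size=1.0)
        mask_arr = np.ones((1, 1, 10), dtype=bool)
        mean, variation, skw, kur = intensity_stats(vol, EmbryoMask(mask_arr, 1, 10, 1.0))
        shifted = vals - vals.min()
        assert mean == pytest.approx(shifted.mean())
        assert variation == pytest.approx(shifted.std(ddof=1) / shifted.mean())
        assert skw == pytest.approx(skew(shifted, bias=False))
        assert kur == pytest.approx(kurtosis(shifted, fisher=True, bias=False))

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(10, 50, 64)
        vol1 = Volume(vals.reshape(4, 4, 4), voxel_size=1.0)
        vol2 = Volume(2 * vals.reshape(4, 4, 4), voxel_size=1.0)
        mask = EmbryoMask(np.ones((4, 4, 4), dtype=bool), 1, 64, 1.0)
        s1 = intensity_stats(vol1, mask)
        s2 = intensity_stats(vol2, mask)
        assert s2[0] == pytest.approx(2 * s1[0])
        np.testing.assert_allclose(s2[1:], s1[1:], rtol=1e-9)

    def test_constant_intensity_reports_missing(self):
        vol = Volume(np.full((3, 3, 3), 5.0), voxel_size=1.0)
        mask = EmbryoMask(np.ones((3, 3, 3), dtype=bool), 1, 27, 1.0)
        mean, variation, skw, kur = intensity_stats(vol, mask)
        assert mean == 0.0
        assert np.isnan(variation) and np.isnan(skw) and np.isnan(kur)


class TestDescriptorVector:
    def test_exactly_26_descriptors(self, default_phantom):
        vol, truth = default_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), mask)
        dv = compute_descriptor_vector(vol, mask, lm, "e1", "wt")
        assert len(dv.descriptors) == 26
        assert tuple(dv.descriptors) == DEFAULT_DESCRIPTOR_NAMES

    def test_translation_invariance(self, small_phantom):
        vol, truth = small_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), mask)
        dv = compute_descriptor_vector(vol, mask, lm, "a", "g")

        shift = (5, 7, 3)
        big = np.zeros((3,) + tuple(np.array(vol.data.shape[1:]) + np.array(shift)))
        big[:, shift[0]:, shift[1]:, shift[2]:] = vol.data
        vol2 = MultichannelVolume(big, voxel_size=vol.voxel_size,
                                  channel_labels=vol.channel_labels)
        mask2_arr = np.zeros(big.shape[1:], dtype=bool)
        mask2_arr[shift[0]:, shift[1]:, shift[2]:] = truth.mask
        mask2 = EmbryoMask(mask2_arr, 1, int(mask2_arr.sum()), vol.voxel_size)
        lm2 = detect_landmarks(vol2.channel("anterior"), vol2.channel("posterior"),
                               mask2)
        dv2 = compute_descriptor_vector(vol2, mask2, lm2, "a", "g")
        for name in DEFAULT_DESCRIPTOR_NAMES:
            assert dv2.descriptors[name] == pytest.approx(
                dv.descriptors[name], rel=1e-6, nan_ok=True), name

    def test_axis_aligned_rotation_within_two_percent(self, small_phantom):
        vol, truth = small_phantom
        mask = EmbryoMask(truth.mask, 1, int(truth.mask.sum()), vol.voxel_size)
        lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), mask)
        dv = compute_descriptor_vector(vol, mask, lm, "a", "g")

        rot = np.stack([np.rot90(vol.data[c], k=1, axes=(1, 2)) for c in range(3)])
        vol2 = MultichannelVolume(rot, voxel_size=vol.voxel_size,
                                  channel_labels=vol.channel_labels)
        mask2_arr = np.rot90(truth.mask, k=1, axes=(1, 2))
        mask2 = EmbryoMask(mask2_arr, 1, int(mask2_arr.sum()), vol.voxel_size)
        lm2 = detect_landmarks(vol2.channel("anterior"), vol2.channel("posterior"),
                               mask2)
        dv2 = compute_descriptor_vector(vol2, mask2, lm2, "a", "g")
        for name in DEFAULT_DESCRIPTOR_NAMES:
            v1, v2 = dv.descriptors[name], dv2.descriptors[name]
            if name == "ap_index":  # bounded in [-1, 1]; compare absolutely
                assert v2 == pytest.approx(v1, abs=0.02)
            else:
                assert v2 == pytest.approx(v1, rel=0.02, nan_ok=True), name

    def test_bounded_descriptors_within_ranges(self, cohort_descriptors):
        table, _, _ = cohort_descriptors
        assert table["solidity"].between(0, 1).all()
        assert table["tortuosity"].ge(1).all()
        assert table["ap_index"].between(-1, 1).all()
        assert (table["axis_length_L1_um"] >= table["axis_length_L2_um"]).all()
        assert (table["axis_length_L2_um"] >= table["axis_length_L3_um"]).all()
        for col in ("axis_ratio_L2_L1", "axis_ratio_L3_L1", "axis_ratio_L3_L2"):
            assert table[col].between(0, 1).all()
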