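import math

import numpy as np
import pytest
from scipy import ndimage

from telopirna.nuclear_geometry import (
    NucleusMask,
    VolumeImage,
    center_of_mass,
    cluster_diameter,
    colocalization_fraction,
    distance_to_surface,
    segment_channel,
    segment_nucleus,
    two_sample_t,
)
from telopirna.seq_io import InputError

ISO = (0.5, 0.5, 0.5)


def _volume(data, voxel_size=ISO):
    return VolumeImage(data=np.asarray(data, dtype=float), voxel_size=voxel_size)


def _random_blob_mask(rng, shape=(14, 16, 15)):
    """A random connected blob: union of a few digitized balls."""
    zz, yy, xx = np.indices(shape)
    mask = np.zeros(shape, dtype=bool)
    c0 = np.array(shape) / 2
    for _ in range(4):
        c = c0 + rng.integers(-3, 4, size=3)
        r = rng.integers(3, 6)
        mask |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r**2
    return mask


def _surface_oracle(mask):
    """Independent 6-neighbor surface detection by explicit looping."""
    out = set()
    Z, Y, X = mask.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not (0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X) or not mask[nz, ny, nx]:
                        out.add((z, y, x))
                        break
    return out


class TestSegmentation:
    def test_two_bright_cubes_make_two_spots(self):
        data = np.zeros((6, 20, 20))
        data[1:3, 2:5, 2:5] = 10.0
        data[3:5, 12:16, 12:16] = 8.0
        spots = segment_channel(_volume(data), "fixed", threshold=1.0)
        assert len(spots) == 2
        assert sorted(s.n_voxels for s in spots.spots) == [2 * 3 * 3, 2 * 4 * 4]

    def test_min_voxels_filters_small_components(self):
        data = np.zeros((4, 8, 8))
        data[1, 1, 1] = 5.0
        spots = segment_channel(_volume(data), "fixed", threshold=1.0, min_voxels=2)
        assert len(spots) == 0

    def test_all_zero_volume_gives_empty_spotset(self):
        spots = segment_channel(_volume(np.zeros((3, 5, 5))), "fixed", threshold=0.5)
        assert len(spots) == 0

    def test_labels_match_flood_fill_oracle(self, rng):
        data = (_random_blob_mask(rng) * 7.0) + (_random_blob_mask(rng, (14, 16, 15)) * 0)
        vol = _volume(data)
        spots = segment_channel(vol, "fixed", threshold=1.0)
        oracle_labels, n = ndimage.label(data > 1.0,
                                         structure=np.ones((3, 3, 3), dtype=bool))
        assert len(spots) == n
        got = {frozenset(map(tuple, s.voxels)) for s in spots.spots}
        want = {
            frozenset(map(tuple, np.argwhere(oracle_labels == i)))
            for i in range(1, n + 1)
        }
        assert got == want

    def test_nucleus_segmentation_fills_holes_and_keeps_largest(self):
        data = np.zeros((8, 20, 20))
        data[1:7, 2:14, 2:14] = 50.0
        data[3:5, 6:9, 6:9] = 0.0  # internal hole
        data[1, 17, 17] = 60.0  # small distractor component
        nucleus = segment_nucleus(_volume(data), "fixed", threshold=10.0)
        assert nucleus.mask[4, 7, 7]  # hole filled
        assert not nucleus.mask[1, 17, 17]  # distractor dropped


class TestCenterOfMass:
    def test_single_voxel_closed_form(self):
        data = np.zeros((4, 6, 8))
        data[2, 3, 4] = 5.0
        vol = _volume(data, voxel_size=(1.05, 0.2, 0.2))
        com = center_of_mass(np.array([[2, 3, 4]]), vol)
        assert com == pytest.approx((2.625, 0.7, 0.9))

    def test_two_equal_voxels_give_midpoint(self):
        data = np.zeros((4, 6, 8))
        data[1, 1, 1] = data[3, 1, 1] = 2.0
        com = center_of_mass(np.array([[1, 1, 1], [3, 1, 1]]), _volume(data))
        assert com == pytest.approx((1.25, 0.75, 0.75))

    def test_zero_intensity_is_undefined(self):
        assert center_of_mass(np.array([[0, 0, 0]]), _volume(np.zeros((2, 2, 2)))) is None

    def test_matches_weighted_mean_oracle(self, rng):
        data = rng.random((6, 7, 8)) + 0.1
        vol = _volume(data, voxel_size=(1.05, 0.3, 0.25))
        voxels = np.argwhere(rng.random((6, 7, 8)) < 0.4)
        com = np.asarray(center_of_mass(voxels, vol))
        w = np.array([data[tuple(v)] for v in voxels])
        want = np.array(
            [sum(w * ((voxels[:, ax] + 0.5) * vol.voxel_size[ax])) / w.sum()
             for ax in range(3)]
        )
        np.testing.assert_allclose(com, want, atol=1e-9)

    def test_unweighted_option_ignores_intensity(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1], data[3, 1, 1] = 1.0, 99.0
        voxels = np.array([[1, 1, 1], [3, 1, 1]])
        com = center_of_mass(voxels, _volume(data), weighted=False)
        assert com[0] == pytest.approx(1.25)


class TestDistanceToSurface:
    def test_digitized_ball_center_distance(self):
        # ball radius 10 um, isotropic 0.5 um voxels
        n = 45
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2
        mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= 20.0**2
        nucleus = NucleusMask(mask, ISO)
        center_um = ((c + 0.5) * 0.5,) * 3
        d = distance_to_surface(center_um, nucleus)
        assert abs(d - 10.0) <= math.sqrt(3) * 0.5  # one voxel diagonal

    def test_point_one_voxel_inside_flat_boundary(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        nucleus = NucleusMask(mask, ISO)
        # voxel (5,5,3) center: one voxel in from the x face at index 2
        d = distance_to_surface(((5.5) * 0.5, 5.5 * 0.5, 3.5 * 0.5), nucleus)
        assert abs(d - 0.5) <= 0.25

    def test_outside_point_is_negative_flagged(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        nucleus = NucleusMask(mask, ISO)
        assert distance_to_surface((0.1, 0.1, 0.1), nucleus) < 0

    def test_matches_brute_force_oracle_exactly(self, rng):
        """The accelerated path must equal the defining brute-force min over
        surface voxels bit for bit (smaller scale here)."""
        for _ in range(5):
            mask = _random_blob_mask(rng)
            voxel_size = (1.05, 0.31, 0.27)
            nucleus = NucleusMask(mask, voxel_size)
            interior = np.argwhere(mask)
            surface = _surface_oracle(mask)
            for _ in range(6):
                idx = interior[rng.integers(len(interior))]
                p = (idx + 0.5) * np.asarray(voxel_size)
                want = min(
                    math.sqrt(sum(((s[i] + 0.5) * voxel_size[i] - p[i]) ** 2
                                  for i in range(3)))
                    for s in surface
                )
                assert distance_to_surface(tuple(p), nucleus) == want

    def test_translation_and_axis_permutation_equivariance(self, rng):
        mask = _random_blob_mask(rng)
        vs = (1.05, 0.3, 0.3)
        idx = np.argwhere(mask)[3]
        p = (idx + 0.5) * np.asarray(vs)
        d0 = distance_to_surface(tuple(p), NucleusMask(mask, vs))
        # translate by 2 voxels along y
        shifted = np.roll(mask, 2, axis=1)
        d1 = distance_to_surface((p[0], p[1] + 2 * vs[1], p[2]),
                                 NucleusMask(shifted, vs))
        assert d1 == pytest.approx(d0, abs=1e-12)
        # permute axes (z <-> x) with matching voxel-size permutation
        perm = np.transpose(mask, (2, 1, 0))
        d2 = distance_to_surface((p[2], p[1], p[0]),
                                 NucleusMask(perm, (vs[2], vs[1], vs[0])))
        assert d2 == pytest.approx(d0, abs=1e-12)


class TestDiameterColocT:
    def test_symmetric_spot_diameter(self):
        data = np.zeros((5, 41, 41))
        zz, yy, xx = np.indices(data.shape)
        data[(zz == 2) & ((yy - 20) ** 2 + (xx - 20) ** 2 <= 16)] = 5.0
        vol = _volume(data, voxel_size=(1.0, 0.5, 0.5))
        spots = segment_channel(vol, "fixed", threshold=1.0)
        center = (2.5, 20.5 * 0.5, 20.5 * 0.5)
        d = cluster_diameter(spots.spots, center, vol.voxel_size)
        assert d == pytest.approx(2 * 4 * 0.5, abs=0.5)

    def test_single_voxel_spot_floors_at_voxel_diagonal(self):
        data = np.zeros((3, 5, 5))
        data[1, 2, 2] = 9.0
        vol = _volume(data, voxel_size=(1.0, 0.4, 0.4))
        spots = segment_channel(vol, "fixed", threshold=1.0)
        center = (1.5, 2.5 * 0.4, 2.5 * 0.4)
        assert cluster_diameter(spots.spots, center, vol.voxel_size) == pytest.approx(
            math.hypot(0.4, 0.4)
        )

    def test_matches_max_distance_scan(self, rng):
        data = np.zeros((6, 30, 30))
        for _ in range(3):
            z, y, x = rng.integers(0, 6), rng.integers(5, 25), rng.integers(5, 25)
            data[z, y - 2 : y + 3, x - 2 : x + 3] = 5.0
        vol = _volume(data, voxel_size=(1.05, 0.2, 0.2))
        spots = segment_channel(vol, "fixed", threshold=1.0)
        all_vox = np.vstack([s.voxels for s in spots.spots])
        center = center_of_mass(all_vox, vol)
        got = cluster_diameter(spots.spots, center, vol.voxel_size)
        z_slice = int(center[0] / 1.05)
        sel = all_vox[all_vox[:, 0] == z_slice]
        if sel.size:
            want = 2 * max(
                math.hypot((v[1] + 0.5) * 0.2 - center[1], (v[2] + 0.5) * 0.2 - center[2])
                for v in sel
            )
            assert got == pytest.approx(max(want, math.hypot(0.2, 0.2)))

    def test_colocalization_full_and_disjoint(self):
        a = np.zeros((4, 10, 10))
        a[1, 2:4, 2:4] = 5.0
        b_mask = np.zeros((4, 10, 10), dtype=bool)
        b_mask[1, 1:6, 1:6] = True
        spots_a = segment_channel(_volume(a), "fixed", threshold=1.0)
        assert colocalization_fraction(spots_a, b_mask)["fraction"] == 1.0
        assert colocalization_fraction(spots_a, ~b_mask & False)["fraction"] == 0.0

    def test_planted_seven_of_ten_overlap(self):
        a = np.zeros((3, 12, 60))
        b = np.zeros((3, 12, 60), dtype=bool)
        for i in range(10):
            a[1, 4:7, 6 * i + 1 : 6 * i + 4] = 5.0
            if i < 7:
                b[1, 4:7, 6 * i + 1 : 6 * i + 4] = True
        spots_a = segment_channel(_volume(a), "fixed", threshold=1.0)
        res = colocalization_fraction(spots_a, b)
        assert (res["n_coloc"], res["n_total"], res["fraction"]) == (7, 10, 0.7)

    def test_empty_a_reports_na(self):
        empty = segment_channel(_volume(np.zeros((2, 4, 4))), "fixed", threshold=1.0)
        assert colocalization_fraction(empty, np.zeros((2, 4, 4), bool))["fraction"] is None

    def test_identical_groups_give_t_zero_p_one(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        g1 = [1.0, 2.0, 3.0, 1.5, 2.5]
        g2 = [v + 10 for v in g1]
        assert two_sample_t(g1, g2)["p"] < 0.01

    def test_welch_matches_textbook_formula(self, rng):
        g1 = rng.normal(0, 1, size=12)
        g2 = rng.normal(0.5, 2, size=9)
        res = two_sample_t(g1, g2, variant="welch")
        v1, v2 = g1.var(ddof=1) / len(g1), g2.var(ddof=1) / len(g2)
        t = (g1.mean() - g2.mean()) / math.sqrt(v1 + v2)
        dof = (v1 + v2) ** 2 / (v1**2 / (len(g1) - 1) + v2**2 / (len(g2) - 1))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), dof)
        assert res["t"] == pytest.approx(t, abs=1e-9)
        assert res["dof"] == pytest.approx(dof, abs=1e-9)
        assert res["p"] == pytest.approx(p, abs=1e-9)

    def test_degenerate_zero_variance(self):
        res = two_sample_t([1.0, 1.0], [1.0, 1.0])
        assert res["degenerate"] and res["p"] is None
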