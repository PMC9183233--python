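"""Spot localization, histone window, spot mobility, nuclear axes, and cell
shape/contact metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import ms2gastrula as m
from ms2gastrula import spotchrom as sc
from ms2gastrula.spotchrom import SpotParams


@pytest.fixture(scope="module")
def rendered_spot():
    """One always-ON nucleus rendered without noise, plus its true spot."""
    geom = m.StripeGeometry(x_extent=20, y_me=10, mse_offset=5, ne_offset=8,
                            spacing=5, jitter=0.0)
    cfg = m.SimConfig(n_mse=1, n_me=1, n_ne=1, stripe_geometry=geom,
                      n_frames=4, noise_sd=0.0, position_noise_sd=0.0,
                      bleach_rate=0.0, p_on=1.0, p_off=0.0, p_step=0.0,
                      t_onset=0.1, onset_spread=0.0, t_constriction=0.3,
                      t_invagination=0.4, t_end=0.7, seed=9)
    table, gt = m.simulate_traces(cfg)
    grid = m.render_stack(gt.trajectories, table, cfg)
    offs = m.synth.spot_offsets(cfg)
    mse_id = gt.nuclei[gt.nuclei.region == "MSE"].nucleus_id.iloc[0]
    return cfg, gt, grid, offs, mse_id


class TestDetectSpotDog:
    def test_rendered_punctum_recovered_within_a_voxel(self, rendered_spot):
        cfg, gt, grid, offs, mse_id = rendered_spot
        f = 2
        row = gt.trajectories.query("frame == @f and nucleus_id == @mse_id"
                                    ).iloc[0]
        true = np.array([row.x_um, row.y_um, row.z_um]) + offs[mse_id]
        cz = int(row.z_um / cfg.voxel_z)
        cy = int(row.y_um / cfg.voxel_xy)
        cx = int(row.x_um / cfg.voxel_xy)
        rz, rxy = 4, 11
        z0 = max(cz - rz, 0)
        sub = grid.channel("spot")[f][z0:cz + rz + 1,
                                      cy - rxy:cy + rxy + 1,
                                      cx - rxy:cx + rxy + 1].astype(float)
        pos = sc.detect_spot_dog(sub, cfg.voxel_xy, cfg.voxel_z)
        origin = np.array([(cx - rxy) * cfg.voxel_xy,
                           (cy - rxy) * cfg.voxel_xy, z0 * cfg.voxel_z])
        err = np.abs(np.array(pos) + origin - true)
        assert err[0] <= cfg.voxel_xy
        assert err[1] <= cfg.voxel_xy
        assert err[2] <= cfg.voxel_z

    def test_uniform_subvolume_yields_none(self):
        assert sc.detect_spot_dog(np.full((8, 20, 20), 7.0), 0.36, 1.0) is None

    def test_invariant_to_additive_constant(self, rendered_spot):
        cfg, gt, grid, _, _ = rendered_spot
        sub = grid.channel("spot")[2][:, 4:26, 20:42].astype(float)
        a = sc.detect_spot_dog(sub, cfg.voxel_xy, cfg.voxel_z)
        b = sc.detect_spot_dog(sub + 500.0, cfg.voxel_xy, cfg.voxel_z)
        assert a is not None and np.allclose(a, b)


class TestHisWindowMean:
    def test_uniform_field(self):
        assert sc.his_window_mean(np.full((20, 20), 3.0), (10, 10)) == 3.0

    def test_5x5_values_1_to_25(self):
        img = np.arange(1, 26, dtype=float).reshape(5, 5)
        assert sc.his_window_mean(img, (2, 2)) == 13.0

    def test_corner_clips_to_valid_quadrant(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        expect = img[0:3, 0:3].mean()
        assert sc.his_window_mean(img, (0, 0)) == expect

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_window_average_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((17, 23))
        y, x = int(rng.integers(0, 17)), int(rng.integers(0, 23))
        vals = [img[yy, xx]
                for yy in range(max(0, y - 2), min(17, y + 3))
                for xx in range(max(0, x - 2), min(23, x + 3))]
        assert sc.his_window_mean(img, (y, x)) == pytest.approx(
            sum(vals) / len(vals))


class TestSpotMobility:
    def _frames(self, offsets, drift=0.0):
        n = len(offsets)
        cents = pd.DataFrame({"frame": range(n),
                              "x_um": np.arange(n) * drift,
                              "y_um": 0.0, "z_um": 0.0})
        spots = cents.copy()
        spots["x_um"] = spots["x_um"] + [o[0] for o in offsets]
        spots["y_um"] = [o[1] for o in offsets]
        return spots, cents

    def test_rigid_comotion_is_zero(self):
        spots, cents = self._frames([(1.0, 0.5)] * 10, drift=2.0)
        out = sc.spot_mobility(spots, cents, 15.0)
        assert np.allclose(out.rel_speed, 0.0)

    def test_half_micron_per_frame_is_two_per_minute(self):
        offsets = [(0.5 * i, 0.0) for i in range(10)]
        spots, cents = self._frames(offsets)
        out = sc.spot_mobility(spots, cents, 15.0,
                               SpotParams(mobility_smooth=1))
        assert np.allclose(out.rel_speed, 2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        offsets = [tuple(rng.uniform(-1, 1, 2)) for _ in range(12)]
        a = sc.spot_mobility(*self._frames(offsets, drift=0.0), 15.0)
        b = sc.spot_mobility(*self._frames(offsets, drift=5.0), 15.0)
        assert np.allclose(a.rel_speed, b.rel_speed, equal_nan=True)

    def test_gap_yields_nan_speed(self):
        spots, cents = self._frames([(0.1 * i, 0.0) for i in range(6)])
        spots = spots[spots.frame != 3]
        cents = cents[cents.frame != 3]
        out = sc.spot_mobility(spots, cents, 15.0,
                               SpotParams(mobility_smooth=1))
        assert np.isnan(out[out.frame == 4].rel_speed.iloc[0])

    def test_single_frame_rejected(self):
        spots, cents = self._frames([(0.0, 0.0)])
        with pytest.raises(ValueError):
            sc.spot_mobility(spots, cents, 15.0)


class TestNuclearFactorLevels:
    def test_uniform_channel(self):
        labels = np.zeros((2, 4, 8, 8), dtype=int)
        labels[:, 1:3, 1:4, 1:4] = 1
        labels[:, 1:3, 5:8, 5:8] = 2
        chan = np.full(labels.shape, 42.0)
        out = sc.nuclear_factor_levels(chan, labels)
        assert np.allclose(out.mean_intensity, 42.0)
        assert len(out) == 4   # 2 labels x 2 frames

    def test_recovers_rendered_intensities(self, small_render):
        cfg, _, _, grid = small_render
        from ms2gastrula import nucseg
        labels, dets = nucseg.segment_movie(grid.channel("nuclear"),
                                            cfg.voxel_xy, cfg.voxel_z)
        out = sc.nuclear_factor_levels(grid.channel("nuclear"), labels)
        assert (out.mean_intensity > 0).all()

    def test_region_curves_weight_nuclei_equally(self):
        levels = pd.DataFrame({
            "frame": [0, 0, 0], "label": [1, 2, 3],
            "mean_intensity": [10.0, 20.0, 60.0],
            "region": ["MSE", "MSE", "NE"]})
        out = sc.region_curves(levels)
        assert out[out.region == "MSE"].mean_intensity.iloc[0] == 15.0


class TestNuclearAxes:
    @staticmethod
    def _ellipsoid_voxels(semi_um, voxel_xy, voxel_z, n=70):
        zz, yy, xx = np.mgrid[:n, :n, :n].astype(float)
        c = n / 2
        r2 = (((xx - c) * voxel_xy / semi_um[0]) ** 2
              + ((yy - c) * voxel_xy / semi_um[1]) ** 2
              + ((zz - c) * voxel_z / semi_um[2]) ** 2)
        return np.argwhere(r2 <= 1.0)

    def test_sphere_axes_equal_diameter(self):
        vox = self._ellipsoid_voxels((3, 3, 3), 0.36, 0.5)
        axes = sc.nuclear_axes(vox, 0.36, 0.5)
        assert np.allclose(axes, 6.0, rtol=0.05)

    def test_ellipsoid_longest_axis(self):
        vox = self._ellipsoid_voxels((4, 2, 2), 0.36, 0.5)
        axes = sc.nuclear_axes(vox, 0.36, 0.5)
        assert axes[0] == pytest.approx(8.0, rel=0.1)
        assert axes[1] == pytest.approx(4.0, rel=0.1)

    def test_rotation_invariance(self):
        vox = self._ellipsoid_voxels((4, 2, 2), 0.5, 0.5)
        swapped = vox[:, [0, 2, 1]]    # rotate 90° in the y/x plane
        a = sc.nuclear_axes(vox, 0.5, 0.5)
        b = sc.nuclear_axes(swapped, 0.5, 0.5)
        assert np.allclose(a, b, rtol=0.02)

    def test_coplanar_set_zero_third_axis(self):
        vox = np.array([[0, y, x] for y in range(6) for x in range(6)])
        axes = sc.nuclear_axes(vox, 1.0, 1.0)
        assert axes[2] == 0.0

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            sc.nuclear_axes(np.zeros((5, 3)), 1.0, 1.0)


def brute_contact(lab, cell_id, me_ids):
    """Pixel-by-pixel dilation-intersection oracle."""
    h, w = lab.shape

    def dilate(mask):
        out = np.zeros_like(mask)
        for y in range(h):
            for x in range(w):
                if mask[max(0, y - 1):y + 2, max(0, x - 1):x + 2].any():
                    out[y, x] = True
        return out

    cell = dilate(lab == cell_id)
    me = np.zeros((h, w), dtype=bool)
    for i in me_ids:
        if i != cell_id:
            me |= dilate(lab == i)
    return int((cell & me).sum())


class TestCellMetrics:
    def test_adjacent_rectangles_match_oracle(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[5:15, 5:10] = 1
        lab[5:15, 10:15] = 2
        assert (sc.cell_contact_length(lab, 1, [2])
                == brute_contact(lab, 1, [2]))

    def test_distant_cells_zero_contact(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[2:5, 2:5] = 1
        lab[12:15, 12:15] = 2
        assert sc.cell_contact_length(lab, 1, [2]) == 0

    def test_contact_symmetry(self):
        rng = np.random.default_rng(4)
        lab = rng.integers(0, 4, (16, 16))
        lab = ndimage.grey_dilation(lab, size=3)  # blobby labels
        ids = [i for i in np.unique(lab) if i > 0]
        if len(ids) >= 2:
            a, b = ids[0], ids[1]
            assert (sc.cell_contact_length(lab, a, [b])
                    == sc.cell_contact_length(lab, b, [a]))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_labels_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.zeros((32, 32), dtype=int)
        for i in range(1, 5):
            y, x = rng.integers(0, 26, 2)
            lab[y:y + 6, x:x + 6] = i
        ids = [i for i in np.unique(lab) if i > 0]
        cell = ids[0]
        me = ids[1:]
        assert (sc.cell_contact_length(lab, cell, me)
                == brute_contact(lab, cell, me))

    def test_unknown_id_rejected(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[2:4, 2:4] = 1
        with pytest.raises(ValueError):
            sc.cell_contact_length(lab, 9, [1])

    def test_disk_eccentricity_near_zero(self):
        yy, xx = np.mgrid[:41, :41]
        lab = (((yy - 20) ** 2 + (xx - 20) ** 2) <= 15 ** 2).astype(int)
        props = sc.cell_shape_props(lab)
        assert props.eccentricity.iloc[0] < 0.1

    def test_rectangle_area(self):
        lab = np.zeros((60, 60), dtype=int)
        lab[10:20, 10:50] = 1
        props = sc.cell_shape_props(lab, voxel_xy=0.5)
        assert props.area_px.iloc[0] == 400
        assert props.area_um2.iloc[0] == pytest.approx(100.0)

    def test_eccentricity_matches_second_moment_oracle(self):
        rng = np.random.default_rng(7)
        lab = np.zeros((40, 40), dtype=int)
        lab[5:30, 10:18] = 1
        coords = np.argwhere(lab == 1)
        cov = np.cov(coords.T, bias=True)
        lam = np.sort(np.linalg.eigvalsh(cov))
        ecc = np.sqrt(1 - lam[0] / lam[1])
        props = sc.cell_shape_props(lab)
        assert props.eccentricity.iloc[0] == pytest.approx(ecc, abs=1e-6)
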