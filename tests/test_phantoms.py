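"""Phantom factory: anti-aliased rasterization and synthetic CT."""

import numpy as np
import pytest

from petac import (
    CalibrationCurve,
    PhantomSpec,
    add_hot_sphere,
    default_curve,
    hu_to_mu,
    make_phantom,
    make_synthetic_ct,
    mouse_phantom_spec,
    rat_phantom_spec,
)
from petac.phantoms import Fiducial


class TestMakePhantom:
    def test_water_mu_at_cylinder_center(self):
        act, mu = make_phantom(mouse_phantom_spec(grid_shape=(90, 90, 1)))
        assert mu.values[45, 45, 0] == pytest.approx(0.0969)

    def test_zero_concentration_gives_zero_activity(self):
        act, _ = make_phantom(mouse_phantom_spec(activity_concentration=0.0))
        assert np.all(act.values == 0)

    def test_rasterized_area_matches_analytic_disk(self):
        # sum(activity) * voxel_area == concentration * pi R^2, per slice
        spec = rat_phantom_spec(grid_shape=(140, 140, 1))
        act, _ = make_phantom(spec)
        voxel_area = spec.voxel_mm[0] * spec.voxel_mm[1]
        measured = act.values[:, :, 0].sum() * voxel_area
        analytic = spec.activity_concentration * np.pi * (spec.diameter_mm / 2) ** 2
        assert measured == pytest.approx(analytic, rel=5e-3)

    def test_area_error_halves_with_finer_voxels(self):
        analytic = np.pi * 15.0**2

        def area_err(n, h):
            spec = mouse_phantom_spec(grid_shape=(n, n, 1), voxel_mm=(h, h, h))
            act, _ = make_phantom(spec)
            return abs(act.values.sum() * h * h - analytic)

        coarse = area_err(40, 1.0)
        fine = area_err(80, 0.5)
        assert fine <= coarse / 2 + 1e-9

    def test_mu_and_activity_share_support(self):
        act, mu = make_phantom(rat_phantom_spec(grid_shape=(140, 140, 2)))
        assert np.array_equal(act.values > 0, mu.values > 0)

    def test_deterministic(self):
        a1, m1 = make_phantom(rat_phantom_spec())
        a2, m2 = make_phantom(rat_phantom_spec())
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(m1.values, m2.values)

    def test_sphere_outside_cylinder_rejected(self):
        with pytest.raises(ValueError, match="inside the cylinder"):
            rat_phantom_spec(hot_sphere=True, sphere_center_mm=(24.0, 0.0, 0.0))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="exceeds grid extent"):
            PhantomSpec(diameter_mm=50.0, grid_shape=(40, 40, 1), voxel_mm=(1.0,) * 3)

    def test_hot_sphere_ratio_in_rasterized_phantom(self):
        spec = rat_phantom_spec(hot_sphere=True, grid_shape=(140, 140, 8))
        act, _ = make_phantom(spec)
        grid = spec.grid()
        x = grid.centers_mm(0)[:, None, None] - 10.0
        y = grid.centers_mm(1)[None, :, None]
        z = grid.centers_mm(2)[None, None, :]
        interior = x**2 + y**2 + z**2 <= (0.6 * spec.sphere_radius_mm) ** 2
        sphere_mean = act.values[interior].mean()
        background = spec.activity_concentration
        assert sphere_mean / background == pytest.approx(4.0, rel=1e-6)


class TestAddHotSphere:
    def test_ratio_four_scales_background(self):
        spec = rat_phantom_spec(grid_shape=(140, 140, 8), voxel_mm=(0.5, 0.5, 1.0))
        act, _ = make_phantom(spec)
        out = add_hot_sphere(act, (10.0, 0.0, 0.0), 4.0, ratio=4.0)
        # 0.5 MBq/cc background -> 2.0 MBq/cc sphere centre
        i = np.argmin(np.abs(out.centers_mm(0) - 10.0))
        j = np.argmin(np.abs(out.centers_mm(1)))
        k = np.argmin(np.abs(out.centers_mm(2)))
        assert out.values[i, j, k] == pytest.approx(2.0, rel=1e-6)

    def test_ratio_one_is_identity(self):
        act, _ = make_phantom(rat_phantom_spec())
        out = add_hot_sphere(act, (10.0, 0.0, 0.0), 4.0, ratio=1.0)
        assert np.array_equal(out.values, act.values)

    def test_cold_sphere_rejected(self):
        act, _ = make_phantom(rat_phantom_spec())
        with pytest.raises(ValueError, match="ratio >= 1"):
            add_hot_sphere(act, (10.0, 0.0, 0.0), 4.0, ratio=0.5)

    def test_sphere_volume_matches_analytic(self):
        spec = rat_phantom_spec(grid_shape=(140, 140, 16), voxel_mm=(0.5, 0.5, 0.5))
        act, _ = make_phantom(spec)
        r = 4.0
        out = add_hot_sphere(act, (10.0, 0.0, 0.0), r, ratio=2.0)
        excess = out.values - act.values
        voxel_vol = np.prod(spec.voxel_mm)
        vol = excess.sum() * voxel_vol / (0.5 * (2.0 - 1.0))  # background=0.5
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)


class TestSyntheticCT:
    def test_mu_a3_maps_to_hu_zero(self):
        curve = default_curve()
        grid = mouse_phantom_spec(grid_shape=(20, 20, 1), diameter_mm=5.0).grid("mu")
        mu = grid.with_values(np.full(grid.shape, curve.a3), role="mu")
        ct = make_synthetic_ct(mu, curve, noise_sd_hu=0.0)
        assert np.allclose(ct.values, 0.0, atol=1e-9)

    def test_noiseless_round_trip(self):
        curve = default_curve()
        _, mu = make_phantom(rat_phantom_spec(grid_shape=(140, 140, 1)))
        ct = make_synthetic_ct(mu, curve, noise_sd_hu=0.0)
        back = hu_to_mu(ct, curve)
        assert np.max(np.abs(back.values - mu.values)) < 1e-6

    def test_seeded_noise_is_reproducible(self):
        curve = default_curve()
        _, mu = make_phantom(mouse_phantom_spec(grid_shape=(90, 90, 1)))
        a = make_synthetic_ct(mu, curve, noise_sd_hu=15.0, seed=7)
        b = make_synthetic_ct(mu, curve, noise_sd_hu=15.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_unattainable_mu_rejected(self):
        curve = CalibrationCurve(0.0, 1e-4, 0.1, hu_domain=(-1000.0, 1000.0))
        grid = mouse_phantom_spec(grid_shape=(4, 4, 1), diameter_mm=1.0).grid("mu")
        mu = grid.with_values(np.full(grid.shape, 0.5), role="mu")  # above range
        with pytest.raises(ValueError, match="attainable"):
            make_synthetic_ct(mu, curve)


def test_fiducials_add_activity_and_mu():
    spec = mouse_phantom_spec(grid_shape=(90, 90, 4))
    spec.fiducials = (Fiducial((20.0, 0.0, 0.0), radius_mm=1.5, concentration=5.0),)
    act, mu = make_phantom(spec)
    i = np.argmin(np.abs(act.centers_mm(0) - 20.0))
    j = np.argmin(np.abs(act.centers_mm(1)))
    k = np.argmin(np.abs(np.asarray(act.centers_mm(2))))
    assert act.values[i, j, k] > spec.activity_concentration
    assert mu.values[i, j, k] > 0
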