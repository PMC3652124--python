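"""Line-integral engine: chord lengths, ACFs, adjointness, Poisson sampling."""

import numpy as np
import pytest

from petac import (
    PhantomSpec,
    Sinogram,
    SinogramGeometry,
    VoxelImage,
    acf_sinogram,
    attenuated_forward,
    centered_grid,
    make_phantom,
    poisson_sample,
    radon_forward,
)
from petac.projector import get_projector

from conftest import random_image

MU_WATER = 0.0969


def uniform_disk(radius_mm, n=140, h=0.5, value=1.0):
    spec = PhantomSpec(
        diameter_mm=2 * radius_mm,
        length_mm=100.0,
        activity_concentration=value,
        grid_shape=(n, n, 1),
        voxel_mm=(h, h, h),
    )
    return make_phantom(spec)


class TestRadonForward:
    def test_zero_image_zero_sinogram(self, small_geom):
        img = centered_grid((40, 40, 1), 1.0)
        assert np.all(radon_forward(img, small_geom).values == 0)

    def test_central_bin_equals_diameter(self):
        # chord through the centre of a unit disk of radius 25 mm is 50 mm
        act, _ = uniform_disk(25.0)
        geom = SinogramGeometry(n_angles=60, n_bins=175, bin_width_mm=0.5)
        sino = radon_forward(act, geom)
        central = sino.values[:, 87, 0]
        assert np.allclose(central, 50.0, rtol=5e-3)

    def test_offcenter_bin_matches_chord_formula(self):
        # chord at radial offset s is 2*sqrt(R^2 - s^2)
        act, _ = uniform_disk(25.0)
        geom = SinogramGeometry(n_angles=12, n_bins=175, bin_width_mm=0.5)
        sino = radon_forward(act, geom)
        s = geom.s_mm
        inside = np.abs(s) < 20.0
        expected = 2 * np.sqrt(25.0**2 - s[inside] ** 2)
        measured = sino.values[0, inside, 0]
        assert np.allclose(measured, expected, rtol=1e-2, atol=0.3)

    def test_rotational_symmetry(self):
        act, _ = uniform_disk(20.0, n=100)
        geom = SinogramGeometry(n_angles=90, n_bins=101, bin_width_mm=0.5)
        sino = radon_forward(act, geom)
        rows = sino.values[:, :, 0]
        ref = rows.mean(axis=0)
        mask = ref > 0.75 * ref.max()  # central chords; grazing rays excluded
        assert np.all(np.abs(rows[:, mask] - ref[mask]) / ref[mask] < 5e-3)

    def test_linearity(self, small_geom, rng):
        a = random_image(rng)
        b = random_image(rng)
        lhs = radon_forward(a.with_values(2 * a.values + 3 * b.values), small_geom)
        rhs = 2 * radon_forward(a, small_geom).values + 3 * radon_forward(
            b, small_geom
        ).values
        assert np.allclose(lhs.values, rhs, rtol=1e-12, atol=1e-12)

    def test_truncation_rejected(self, small_geom):
        img = centered_grid((120, 120, 1), 1.0)
        vals = np.zeros(img.shape)
        vals[2, 2, 0] = 1.0  # far corner, outside the 81 mm FOV
        with pytest.raises(ValueError, match="field of view"):
            radon_forward(img.with_values(vals), small_geom)


class TestACF:
    def test_zero_mu_gives_unit_acf(self, small_geom):
        mu = centered_grid((40, 40, 1), 1.0, role="mu")
        assert np.allclose(acf_sinogram(mu, small_geom).values, 1.0)

    @pytest.mark.parametrize(
        "radius_mm, expected",
        [(25.0, np.exp(MU_WATER * 5.0)), (15.0, np.exp(MU_WATER * 3.0))],
    )
    def test_water_disk_central_acf(self, radius_mm, expected):
        # exp(mu * diameter_cm): 1.623 for the rat, 1.337 for the mouse size
        _, mu = uniform_disk(radius_mm)  # water mu-map, 0.0969 cm^-1
        geom = SinogramGeometry(n_angles=4, n_bins=175, bin_width_mm=0.5)
        acf = acf_sinogram(mu, geom)
        assert acf.values[:, 87, 0] == pytest.approx(expected, rel=2e-3)

    def test_negative_mu_rejected(self, small_geom):
        img = centered_grid((20, 20, 1), 1.0)
        img = img.with_values(img.values - 1.0)
        with pytest.raises(ValueError):
            acf_sinogram(img, small_geom)

    def test_exponential_additivity(self, small_geom, rng):
        mu1 = random_image(rng).with_values(0.01 * random_image(rng).values, "mu")
        mu2 = random_image(rng).with_values(0.01 * random_image(rng).values, "mu")
        both = mu1.with_values(mu1.values + mu2.values, "mu")
        prod = acf_sinogram(mu1, small_geom).values * acf_sinogram(mu2, small_geom).values
        assert np.allclose(acf_sinogram(both, small_geom).values, prod, rtol=1e-12)


class TestAttenuatedForward:
    def test_zero_mu_reduces_to_radon(self, small_geom, rng):
        act = random_image(rng)
        mu = act.with_values(np.zeros(act.shape), "mu")
        att = attenuated_forward(act, mu, small_geom)
        assert np.array_equal(att.values, radon_forward(act, small_geom).values)

    def test_rat_central_bin_attenuation_factor(self):
        act, mu = uniform_disk(25.0)
        geom = SinogramGeometry(n_angles=4, n_bins=175, bin_width_mm=0.5)
        att = attenuated_forward(act, mu, geom)
        clean = radon_forward(act, geom)
        factor = att.values[0, 87, 0] / clean.values[0, 87, 0]
        assert factor == pytest.approx(np.exp(-MU_WATER * 5.0), rel=2e-3)

    def test_acf_times_attenuated_recovers_radon(self, small_geom, rng):
        act = random_image(rng)
        mu = act.with_values(0.02 * random_image(rng).values, "mu")
        att = attenuated_forward(act, mu, small_geom)
        acf = acf_sinogram(mu, small_geom)
        clean = radon_forward(act, small_geom)
        recovered = att.values * acf.values
        nz = clean.values > 1e-9
        assert np.allclose(recovered[nz], clean.values[nz], rtol=1e-10)

    def test_grid_mismatch_rejected(self, small_geom):
        act = centered_grid((30, 30, 1), 1.0)
        mu = centered_grid((40, 40, 1), 1.0, role="mu")
        with pytest.raises(ValueError, match="same grid"):
            attenuated_forward(act, mu, small_geom)


class TestAdjointness:
    def test_forward_back_adjoint_identity(self, small_geom, rng):
        # <A x, y> == <x, A^T y>, required for EM convergence
        proj = get_projector(small_geom, (32, 32), 1.0)
        for _ in range(5):
            x = rng.random((32, 32))
            y = rng.random((small_geom.n_angles, small_geom.n_bins))
            lhs = np.vdot(proj.forward(x), y)
            rhs = np.vdot(x, proj.back(y))
            assert lhs == pytest.approx(rhs, rel=1e-6)


class TestPoissonSample:
    def test_zero_sinogram_zero_counts(self, small_geom):
        z = Sinogram(np.zeros((60, 81, 1)), small_geom)
        counts = poisson_sample(z, 1e5, seed=0)
        assert counts.kind == "counts"
        assert np.all(counts.values == 0)

    def test_total_counts_within_poisson_error(self, water_disk, small_geom):
        _, act, _ = water_disk
        sino = radon_forward(act, small_geom)
        n = 5e5
        counts = poisson_sample(sino, n, seed=3)
        assert abs(counts.values.sum() / n - 1) < 3 / np.sqrt(n)

    def test_same_seed_same_counts(self, water_disk, small_geom):
        _, act, _ = water_disk
        sino = radon_forward(act, small_geom)
        a = poisson_sample(sino, 1e5, seed=9)
        b = poisson_sample(sino, 1e5, seed=9)
        assert np.array_equal(a.values, b.values)


class TestSinogramInvariants:
    def test_acf_kind_requires_values_ge_one(self, small_geom):
        with pytest.raises(ValueError, match=">= 1"):
            Sinogram(0.5 * np.ones((60, 81)), small_geom, kind="acf")

    def test_counts_kind_requires_nonnegative(self, small_geom):
        with pytest.raises(ValueError, match="nonnegative"):
            Sinogram(-np.ones((60, 81)), small_geom, kind="counts")

    def test_even_bin_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SinogramGeometry(n_angles=10, n_bins=80)
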