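import numpy as np
import pytest

from steroflip import BilayerPotential
from steroflip.constants import thermal_energy
from steroflip.datatypes import PMFProfile, UmbrellaWindow
from steroflip.pmf import (
    boltzmann_invert,
    bootstrap_pmf,
    profile_features,
    wham,
)

RT310 = thermal_energy(310.0)


def harmonic_samples(k, n, seed, center=0.0):
    rng = np.random.default_rng(seed)
    return rng.normal(center, np.sqrt(RT310 / k), n)


class TestBoltzmannInvert:
    def test_uniform_samples_flat_profile(self):
        rng = np.random.default_rng(0)
        prof = boltzmann_invert(rng.uniform(-1, 1, 200_000), bin_width=0.1)
        # counting noise: sigma_G ~ RT/sqrt(n_per_bin); compare demeaned
        # (min-referencing shifts the whole profile by the deepest fluctuation)
        sigma = RT310 / np.sqrt(200_000 / prof.z_grid.size)
        dev = prof.G - np.nanmean(prof.G)
        assert np.nanmax(np.abs(dev)) < 4.0 * sigma

    def test_gaussian_samples_quadratic_curvature(self):
        k = 10.0
        prof = boltzmann_invert(harmonic_samples(k, 1_000_000, seed=1), bin_width=0.05)
        sel = np.isfinite(prof.G) & (np.abs(prof.z_grid) < 1.2)
        coeffs = np.polyfit(prof.z_grid[sel], prof.G[sel], 2)
        assert 2 * coeffs[0] == pytest.approx(k, rel=0.05)

    def test_single_occupied_bin(self):
        prof = boltzmann_invert(np.full(10, 0.42), bin_width=0.05)
        assert np.nanmin(prof.G) == 0.0
        assert np.isfinite(prof.G).sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_invert(np.array([]))


class TestWham:
    def test_single_unbiased_window_equals_inversion(self):
        """WHAM degenerates exactly to Boltzmann inversion for one window."""
        samples = harmonic_samples(10.0, 50_000, seed=2)
        w = UmbrellaWindow(z0=0.0, k_bias=0.0, samples=samples)
        a = wham([w], bin_width=0.05)
        b = boltzmann_invert(samples, bin_width=0.05)
        np.testing.assert_array_equal(a.z_grid, b.z_grid)
        m = np.isfinite(a.G) & np.isfinite(b.G)
        assert m.sum() == np.isfinite(a.G).sum()
        np.testing.assert_allclose(a.G[m], b.G[m], atol=1e-10)

    def test_flat_potential_recovers_flat_profile(self, rng):
        # biased windows over a flat base potential: unbiasing must null the bias
        k = 750.0
        sd = np.sqrt(RT310 / k)
        windows = [
            UmbrellaWindow(z0=0.1 * i, k_bias=k,
                           samples=rng.normal(0.1 * i, sd, 4000))
            for i in range(41)
        ]
        prof, reps = bootstrap_pmf(windows, n_boot=50, seed=3, return_replicates=True)
        sel = np.isfinite(prof.G) & (prof.z_grid > 0.2) & (prof.z_grid < 3.8)
        assert np.max(prof.G[sel]) < 3.0 * np.max(prof.err[sel])

    def test_window_order_invariance(self, rng):
        k = 750.0
        sd = np.sqrt(RT310 / k)
        windows = [
            UmbrellaWindow(z0=0.1 * i, k_bias=k,
                           samples=rng.normal(0.1 * i, sd, 1000))
            for i in range(10)
        ]
        a = wham(windows, tol=1e-12)
        b = wham(windows[::-1], tol=1e-12)
        m = np.isfinite(a.G)
        np.testing.assert_allclose(a.G[m], b.G[m], atol=1e-6)

    def test_nonoverlapping_windows_named(self):
        w1 = UmbrellaWindow(z0=0.0, k_bias=750.0, samples=np.full(50, 0.0))
        w2 = UmbrellaWindow(z0=2.0, k_bias=750.0, samples=np.full(50, 2.0))
        with pytest.raises(ValueError, match="0.000.*2.000"):
            wham([w1, w2])

    def test_nonconvergence_reports_residual(self, cnone_windows):
        with pytest.raises(RuntimeError, match="converge"):
            wham(cnone_windows, max_iter=5)


class TestBootstrap:
    def test_duplicated_constant_samples_zero_error(self):
        wins = [
            UmbrellaWindow(z0=0.0, k_bias=750.0, samples=np.full(100, 0.5)),
            UmbrellaWindow(z0=0.1, k_bias=750.0, samples=np.full(100, 0.5)),
        ]
        prof = bootstrap_pmf(wins, n_boot=2, seed=0)
        np.testing.assert_array_equal(prof.err[np.isfinite(prof.err)], 0.0)

    def test_error_scales_with_sample_size(self):
        """Quadrupling the samples halves the bootstrap error (~1/sqrt(n)).

        A single unbiased Gaussian window keeps the profile's reference
        bin (the density maximum) well sampled, so per-bin errors follow
        pure counting statistics.
        """
        def make(n, seed):
            return [UmbrellaWindow(z0=0.0, k_bias=0.0,
                                   samples=harmonic_samples(10.0, n, seed))]

        def central_err(windows):
            prof = bootstrap_pmf(windows, n_boot=80, seed=1, bin_width=0.1)
            sel = np.isfinite(prof.err) & (np.abs(prof.z_grid) < 1.0)
            return np.median(prof.err[sel])

        ratio = central_err(make(4000, 10)) / central_err(make(16000, 11))
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3

    def test_seed_reproducible(self, cnone_windows):
        sub = cnone_windows[:8]
        a = bootstrap_pmf(sub, n_boot=5, seed=9).err
        b = bootstrap_pmf(sub, n_boot=5, seed=9).err
        np.testing.assert_array_equal(a, b)

    def test_n_boot_validation(self, cnone_windows):
        with pytest.raises(ValueError):
            bootstrap_pmf(cnone_windows[:3], n_boot=1, seed=0)


class TestProfileFeatures:
    @staticmethod
    def toy_profile():
        z = np.linspace(-5, 5, 201)
        g = np.empty_like(z)
        a = np.abs(z)
        g[a <= 2] = 10.0 * (1 - (2 - np.abs(2 - a[a <= 2])) / 2) ** 0  # placeholder
        # monotone ramps: 10 at 0 -> 0 at |z|=2 -> 50 at |z|=4 -> flat
        g = np.where(a <= 2, 10.0 * (1 - a / 2) ** 1, np.minimum(50.0, 25.0 * (a - 2)))
        return PMFProfile(z_grid=z, G=g, temperature=310.0)

    def test_toy_readoff(self):
        f = profile_features(self.toy_profile(), water_region=4.0)
        assert f.z_eq == pytest.approx(2.0, abs=0.06)
        assert f.dG_center == pytest.approx(10.0, abs=0.3)
        assert f.dG_barrier == pytest.approx(10.0, abs=0.3)
        assert f.dG_desorb == pytest.approx(50.0, abs=0.3)

    def test_offcenter_shoulder_barrier_exceeds_center(self):
        z = np.linspace(0, 4, 81)
        # minimum at 2, center 10, shoulder 12 at z=1, plateau 50 beyond 3
        g = np.interp(z, [0.0, 1.0, 2.0, 3.0, 4.0], [10.0, 12.0, 0.0, 50.0, 50.0])
        f = profile_features(PMFProfile(z_grid=z, G=g), water_region=3.0)
        assert f.dG_center == pytest.approx(10.0, abs=0.3)
        assert f.dG_barrier == pytest.approx(12.0, abs=0.3)

    def test_symmetrize_averages_leaflets(self):
        z = np.linspace(-2, 2, 81)
        g = np.where(z < 0, (np.abs(z) - 1) ** 2 * 8, (np.abs(z) - 1) ** 2 * 12) + \
            4.0 * np.exp(-(z / 0.2) ** 2)
        f_sym = profile_features(PMFProfile(z_grid=z, G=g), water_region=1.9, symmetrize=True)
        assert f_sym.z_eq == pytest.approx(1.0, abs=0.1)

    def test_water_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            profile_features(self.toy_profile(), water_region=9.0)


def test_wham_symmetry_property(cnone_potential):
    """Even planted potential: two-sided umbrella set gives |G(z)-G(-z)| small."""
    from steroflip.synthetic import sample_umbrella_windows, umbrella_centers

    centers = umbrella_centers(n_windows=25, spacing=0.1, start=-1.2)
    wins = sample_umbrella_windows(
        BilayerPotential(z_eq=0.8, dG_center=5.0, dG_desorb=40.0, wall_halfwidth=0.3),
        centers=centers, run_time=20.0, equilibration_time=4.0, seed=77,
    )
    prof, reps = bootstrap_pmf(wins, n_boot=50, seed=1, return_replicates=True)
    zg, g, e = prof.z_grid, prof.G, prof.err
    finite = np.isfinite(g)
    mirrored = np.interp(-zg, zg[finite], g[finite])
    err_m = np.interp(-zg, zg[finite], e[finite])
    sel = finite & (np.abs(zg) < 1.1)
    pooled = np.sqrt(e[sel] ** 2 + err_m[sel] ** 2) + 1e-9
    assert np.all(np.abs(g[sel] - mirrored[sel]) < 3.0 * pooled + 0.3)
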