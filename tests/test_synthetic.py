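import numpy as np
import pytest

from steroflip import (
    make_hbond_scene,
    render_gp_image,
    sample_orientations,
    simulate_lateral_diffusion,
)
from steroflip.gp import gp_map
from steroflip.observables import fit_diffusion, msd


class TestOrientations:
    def test_delta_zero_aligns_with_normal(self):
        s = sample_orientations({"kind": "delta", "theta_deg": 0.0}, n=100, seed=0)
        np.testing.assert_allclose(s.vectors[:, 2], 1.0, atol=1e-12)

    def test_delta_ninety_orthogonal_to_normal(self):
        s = sample_orientations({"kind": "delta", "theta_deg": 90.0}, n=100, seed=0)
        np.testing.assert_allclose(s.vectors[:, 2], 0.0, atol=1e-12)

    def test_uniform_sphere_second_moment(self):
        s = sample_orientations({"kind": "uniform-sphere"}, n=100_000, seed=1)
        assert np.mean(s.vectors[:, 2] ** 2) == pytest.approx(1 / 3, rel=0.01)

    def test_cos_histogram_respects_support(self):
        s = sample_orientations(
            {"kind": "cos-histogram", "edges": [0.8, 1.0], "weights": [1.0]},
            n=1000, seed=2,
        )
        assert np.all(s.vectors[:, 2] >= 0.8)

    def test_seed_reproducible(self):
        a = sample_orientations({"kind": "uniform-sphere"}, n=50, seed=3)
        b = sample_orientations({"kind": "uniform-sphere"}, n=50, seed=3)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sample_orientations({"kind": "vonmises"}, n=10, seed=0)
        with pytest.raises(ValueError):
            sample_orientations(
                {"kind": "cos-histogram", "edges": [0, 1], "weights": [1, 1]}, n=10, seed=0
            )


class TestHBondScene:
    @staticmethod
    def _measure(scene, d_id, h_id, a_id):
        """Independent re-measurement with plain trigonometry."""
        d, h, a = (scene.position(i) for i in (d_id, h_id, a_id))
        da = a - d
        dh = h - d
        dist = float(np.sqrt(np.sum(da**2)))
        cosang = np.dot(da, dh) / (dist * np.sqrt(np.sum(dh**2)))
        return dist, float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))

    def test_planted_geometry_is_exact(self):
        scene = make_hbond_scene([(0.30, 10.0), (0.325, 35.0)])
        d, ang = self._measure(scene, 0, 1, 2)
        assert d == pytest.approx(0.30, abs=1e-9)
        assert ang == pytest.approx(10.0, abs=1e-9)
        d, ang = self._measure(scene, 3, 4, 5)
        assert d == pytest.approx(0.325, abs=1e-9)
        assert ang == pytest.approx(35.0, abs=1e-9)

    def test_many_random_geometries_roundtrip(self, rng):
        planted = [(float(rng.uniform(0.1, 0.5)), float(rng.uniform(0, 180)))
                   for _ in range(50)]
        scene = make_hbond_scene(planted)
        for i, (d_req, a_req) in enumerate(planted):
            d, ang = self._measure(scene, 3 * i, 3 * i + 1, 3 * i + 2)
            assert d == pytest.approx(d_req, abs=1e-6)
            assert ang == pytest.approx(a_req, abs=1e-6)

    def test_unphysical_distance_rejected(self):
        with pytest.raises(ValueError):
            make_hbond_scene([(0.0, 10.0)])


class TestLateralDiffusion:
    def test_msd_recovers_planted_d(self):
        tracks = simulate_lateral_diffusion(D=1.0, n_tracks=100, dt=0.01,
                                            n_steps=2000, seed=4)
        curve = msd(tracks, max_lag=200)
        d = fit_diffusion(curve, (curve.lag[1], curve.lag[100]))
        assert d == pytest.approx(1.0, rel=0.10)

    def test_drift_breaks_naive_msd_com_removal_restores(self):
        tracks = simulate_lateral_diffusion(
            D=1.0, n_tracks=100, dt=0.01, n_steps=2000, seed=5,
            leaflet_drift=(1.0, 0.0),
        )
        raw = msd(tracks, max_lag=200)
        d_raw = fit_diffusion(raw, (raw.lag[50], raw.lag[200]))
        assert d_raw > 1.3  # superlinear contamination from drift
        clean = msd(tracks, remove_leaflet_com=True, max_lag=200)
        d_clean = fit_diffusion(clean, (clean.lag[1], clean.lag[100]))
        assert d_clean == pytest.approx(1.0, rel=0.10)

    def test_zero_length_tracks_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            simulate_lateral_diffusion(D=1.0, n_tracks=5, dt=0.01, n_steps=0, seed=0)

    def test_seed_reproducible(self):
        a = simulate_lateral_diffusion(D=0.5, n_tracks=3, dt=0.1, n_steps=10, seed=8)
        b = simulate_lateral_diffusion(D=0.5, n_tracks=3, dt=0.1, n_steps=10, seed=8)
        np.testing.assert_array_equal(a.xy, b.xy)


class TestRenderGP:
    def test_zero_gp_equal_channels(self):
        pair = render_gp_image(np.zeros((8, 8)), total_intensity=np.full((8, 8), 10.0))
        np.testing.assert_array_equal(pair.I_ordered, pair.I_disordered)

    def test_channel_arithmetic(self):
        pair = render_gp_image(np.full((4, 4), 0.5), total_intensity=4.0)
        np.testing.assert_allclose(pair.I_ordered, 3.0)
        np.testing.assert_allclose(pair.I_disordered, 1.0)

    def test_noiseless_roundtrip_identity(self, rng):
        gp_truth = rng.uniform(-0.9, 0.9, size=(16, 16))
        pair = render_gp_image(gp_truth, total_intensity=100.0, g_factor=1.3)
        res = gp_map(pair, mask_threshold=0.0)
        np.testing.assert_allclose(res.gp_map, gp_truth, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            render_gp_image(np.full((2, 2), 1.5), total_intensity=1.0)
        with pytest.raises(ValueError):
            render_gp_image(np.zeros((2, 2)), total_intensity=-1.0)
        with pytest.raises(ValueError):
            render_gp_image(np.zeros((2, 2)), total_intensity=1.0, noise_model="poisson")

    def test_poisson_noise_seeded(self):
        a = render_gp_image(np.zeros((8, 8)), 50.0, noise_model="poisson", seed=1)
        b = render_gp_image(np.zeros((8, 8)), 50.0, noise_model="poisson", seed=1)
        np.testing.assert_array_equal(a.I_ordered, b.I_ordered)
        assert not np.array_equal(
            a.I_ordered,
            render_gp_image(np.zeros((8, 8)), 50.0, noise_model="poisson", seed=2).I_ordered,
        )
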