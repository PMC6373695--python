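"""Ray tracing, line integrals, Beer-Lambert projection and detector noise."""

import logging

import numpy as np
import pytest

import priorphase as pp
from conftest import box_chord_length, sampled_line_integral


def _random_outside_point(rng, volume, scale=3.0):
    low, high = volume.bounds()
    span = high - low
    center = 0.5 * (low + high)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return center + direction * scale * span.max()


class TestTraceRay:
    def test_missing_ray_is_empty(self, small_random_volume):
        path = pp.trace_ray(small_random_volume, (500.0, 500.0, 500.0),
                            (500.0, 400.0, 500.0))
        assert len(path.lengths) == 0
        assert path.total_length == 0.0

    def test_axis_aligned_chord_equals_extent(self):
        vol = pp.VoxelVolume(np.ones((10, 12, 14)), spacing=(2.0, 1.0, 1.0))
        path = pp.trace_ray(vol, (-100.0, 0.0, 0.0), (100.0, 0.0, 0.0))
        assert path.total_length == pytest.approx(10 * 2.0, abs=1e-9)

    def test_random_oblique_rays_match_analytic_chord(self, small_random_volume):
        rng = np.random.default_rng(0)
        for _ in range(25):
            src = _random_outside_point(rng, small_random_volume)
            dst = _random_outside_point(rng, small_random_volume)
            path = pp.trace_ray(small_random_volume, src, dst)
            chord = box_chord_length(small_random_volume, src, dst)
            assert path.total_length == pytest.approx(chord, abs=1e-6)

    def test_voxels_visited_in_traversal_order(self, small_random_volume):
        src = np.array([-200.0, 1.0, 2.0])
        dst = np.array([200.0, 3.0, 1.0])
        path = pp.trace_ray(small_random_volume, src, dst)
        x_idx = path.voxel_indices[:, 0]
        assert np.all(np.diff(x_idx) >= 0)

    def test_degenerate_inputs_raise(self, small_random_volume):
        with pytest.raises(ValueError):
            pp.trace_ray(small_random_volume, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            pp.trace_ray(small_random_volume, (0.0, 0.0, 0.0), (100.0, 0.0, 0.0))


class TestLineIntegral:
    def test_zero_volume_gives_zero(self):
        vol = pp.VoxelVolume(np.zeros((8, 8, 8)))
        path = pp.trace_ray(vol, (-50.0, 0.0, 0.0), (50.0, 0.0, 0.0))
        assert pp.line_integral(path, vol) == 0.0

    def test_uniform_volume_factorizes(self):
        mu = 0.31
        vol = pp.VoxelVolume(np.full((16, 16, 16), mu), spacing=(1.0, 1.0, 1.0))
        path = pp.trace_ray(vol, (-50.0, 0.1, -0.2), (50.0, -0.3, 0.4))
        assert pp.line_integral(path, vol) == pytest.approx(
            mu * path.total_length, rel=1e-12
        )

    def test_matches_dense_sampling_oracle(self, small_random_volume):
        rng = np.random.default_rng(1)
        for _ in range(6):
            src = _random_outside_point(rng, small_random_volume)
            dst = _random_outside_point(rng, small_random_volume)
            path = pp.trace_ray(small_random_volume, src, dst)
            got = pp.line_integral(path, small_random_volume)
            if got < 1.0:  # grazing rays: relative tolerance meaningless
                continue
            want = sampled_line_integral(small_random_volume, src, dst)
            assert got == pytest.approx(want, rel=1e-3)

    def test_additivity_in_attenuation(self, small_random_volume):
        rng = np.random.default_rng(2)
        other = pp.VoxelVolume(rng.uniform(0, 1, small_random_volume.shape),
                               spacing=small_random_volume.spacing)
        both = pp.VoxelVolume(small_random_volume.values + other.values,
                              spacing=small_random_volume.spacing)
        src, dst = (-100.0, 2.0, 1.0), (100.0, -1.0, 3.0)
        path = pp.trace_ray(both, src, dst)
        assert pp.line_integral(path, both) == pytest.approx(
            pp.line_integral(path, small_random_volume) + pp.line_integral(path, other),
            rel=1e-12,
        )

    def test_out_of_range_index_raises(self, small_random_volume):
        path = pp.RayPath(np.array([[100, 0, 0]]), np.array([1.0]))
        with pytest.raises(IndexError):
            pp.line_integral(path, small_random_volume)


class TestForwardProject:
    geom = pp.ConeBeamGeometry(sad=300.0, sdd=500.0, detector_pixels=(32, 32),
                               pixel_pitch=(4.0, 4.0))

    def test_zero_volume_gives_source_intensity(self):
        vol = pp.VoxelVolume(np.zeros((16, 16, 16)), spacing=(2.0, 2.0, 2.0))
        proj = pp.forward_project(vol, self.geom, 30.0, source_intensity=2.5)
        np.testing.assert_allclose(proj.intensities, 2.5, atol=1e-12)

    def test_uniform_cube_beer_lambert_central_pixel(self):
        mu = 0.01
        vol = pp.VoxelVolume(np.full((32, 32, 32), mu), spacing=(2.0, 2.0, 2.0))
        proj = pp.forward_project(vol, self.geom, 0.0, source_intensity=1.0)
        # central ray crosses the 64 mm cube along y
        central = proj.intensities[15:17, 15:17].mean()
        src = self.geom.source_position(0.0)
        centers = self.geom.pixel_centers(0.0)
        expected = np.exp(-mu * box_chord_length(vol, src, centers[16, 16]))
        assert central == pytest.approx(expected, rel=1e-3)

    def test_intensities_bounded_by_source(self, small_random_volume):
        proj = pp.forward_project(small_random_volume, self.geom, 77.0,
                                  source_intensity=3.0)
        assert np.all(proj.intensities > 0.0)
        assert np.all(proj.intensities <= 3.0 + 1e-12)

    def test_monotone_in_attenuation(self, small_random_volume):
        denser = pp.VoxelVolume(small_random_volume.values * 2.0,
                                spacing=small_random_volume.spacing)
        a = pp.forward_project(small_random_volume, self.geom, 0.0)
        b = pp.forward_project(denser, self.geom, 0.0)
        crossing = a.intensities < 1.0 - 1e-9
        assert np.all(b.intensities[crossing] < a.intensities[crossing])

    def test_roi_projection_matches_full_crop(self, small_random_volume):
        roi = pp.ROISpec(u_min=5, u_max=15, v_min=8, v_max=20)
        full = pp.forward_project(small_random_volume, self.geom, 12.0)
        part = pp.forward_project(small_random_volume, self.geom, 12.0, roi=roi)
        np.testing.assert_allclose(part.intensities, roi.crop(full.intensities),
                                   rtol=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            pp.ConeBeamGeometry(sad=500.0, sdd=400.0)
        with pytest.raises(ValueError):
            pp.forward_project(
                pp.VoxelVolume(np.zeros((8, 8, 8))), self.geom, 0.0,
                source_intensity=0.0,
            )


class TestAddNoise:
    def _proj(self):
        rng = np.random.default_rng(5)
        return pp.ProjectionImage(rng.uniform(0.2, 1.0, (20, 20)), angle=0.0,
                                  source_intensity=1.0)

    def test_seeded_determinism(self):
        p = self._proj()
        a = pp.add_noise(p, 1e4, seed=11)
        b = pp.add_noise(p, 1e4, seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_high_fluence_converges_to_noiseless(self):
        p = self._proj()
        noisy = pp.add_noise(p, 1e6, seed=1)
        rel_rms = np.sqrt(np.mean((noisy.intensities - p.intensities) ** 2
                                  / p.intensities**2))
        assert rel_rms < 0.01  # ~1/sqrt(N) scaling at N ~ 1e6

    def test_mean_over_replicates_is_unbiased(self):
        p = self._proj()
        photons = 1000.0
        pixel = (3, 7)
        vals = np.array([
            pp.add_noise(p, photons, seed=s).intensities[pixel] for s in range(1000)
        ])
        lam = p.intensities[pixel] * photons
        se = np.sqrt(lam) / photons / np.sqrt(len(vals))
        assert abs(vals.mean() - p.intensities[pixel]) < 3.0 * se

    def test_invalid_photons_raise(self):
        with pytest.raises(ValueError):
            pp.add_noise(self._proj(), 0.0)


class TestLogTransform:
    def test_unattenuated_maps_to_zero(self):
        p = pp.ProjectionImage(np.full((8, 8), 2.0), angle=0.0, source_intensity=2.0)
        np.testing.assert_allclose(pp.log_transform(p), 0.0, atol=1e-12)

    def test_inverts_forward_projection(self, small_random_volume):
        geom = TestForwardProject.geom
        proj = pp.forward_project(small_random_volume, geom, 45.0,
                                  source_intensity=2.0)
        g = pp.log_transform(proj)
        back = 2.0 * np.exp(-g)
        np.testing.assert_allclose(back, proj.intensities, atol=1e-9)

    def test_monotone_decreasing_in_intensity(self):
        p = pp.ProjectionImage(np.array([[0.1, 0.5], [0.9, 1.0]]), angle=0.0)
        g = pp.log_transform(p)
        assert g[0, 0] > g[0, 1] > g[1, 0] > g[1, 1]

    def test_nonpositive_pixels_clamped_with_warning(self, caplog):
        p = pp.ProjectionImage(np.array([[0.0, 0.5], [1.0, 1.0]]), angle=0.0)
        with caplog.at_level(logging.WARNING):
            g = pp.log_transform(p)
        assert np.isfinite(g).all()
        assert any("clamping" in r.message for r in caplog.records)
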