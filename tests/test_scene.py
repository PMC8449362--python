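"""Synthetic scene generator: helix geometry, placement, imaging model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from pseudopodtomo.scene import (HelicalParams, ReceptorSpec, SceneError,
                                 SceneSpec, TubeSpec,
                                 axial_autocorrelation_peak,
                                 build_actin_density, generate_scene,
                                 helix_subunit_coords, missing_wedge_filter,
                                 place_filaments, place_membrane_and_receptors)


class TestHelixGeometry:
    def test_consecutive_subunits_separated_by_one_rise(self, helical_default):
        coords = helix_subunit_coords(helical_default, 50.0)
        dx = np.diff(coords[:, 0])
        assert np.allclose(dx, 2.76), "axial spacing must equal the 27.6 A rise"

    def test_subunit_azimuth_steps_by_twist(self, helical_default):
        coords = helix_subunit_coords(helical_default, 30.0)
        ang = np.degrees(np.arctan2(coords[:, 2], coords[:, 1]))
        step = np.diff(ang) % 360.0
        assert np.allclose(step, (-166.7) % 360.0, atol=1e-6)

    def test_degenerate_short_filament_is_single_subunit(self, helical_default):
        coords = helix_subunit_coords(helical_default, 1.0)  # < one rise
        assert coords.shape == (1, 3)
        assert np.allclose(coords[0, 0], 0.0)

    def test_invalid_pixel_size_rejected(self, helical_default):
        with pytest.raises(SceneError):
            build_actin_density(helical_default, 50.0, pixel_size=0.0)

    @pytest.mark.parametrize("bad", [
        dict(rise=0.0), dict(twist=0.0), dict(twist=200.0),
        dict(subunit_radius=-1.0), dict(subunit_sigma=0.0),
    ])
    def test_invalid_helical_params_rejected(self, bad):
        with pytest.raises(SceneError):
            HelicalParams(**bad)

    def test_axial_autocorrelation_peaks_at_the_rise(self, helical_default):
        """The lattice repeat of the noise-free filament reads out at
        27.6 A (within half the rasterization voxel)."""
        peak = axial_autocorrelation_peak(helical_default, length_nm=100.0,
                                          sample_a=0.5, pixel_size=0.25)
        assert abs(peak - 27.6) <= 1.25


class TestFilamentPlacement:
    def test_tip_fraction_one_makes_every_trace_tipward(self):
        spec = SceneSpec(tip_fraction=1.0, n_filaments=(10, 10), seed=3)
        traces = place_filaments(spec)
        for tr in traces:
            assert tr.barbed_direction()[0] > 0

    def test_tip_fraction_zero_makes_every_trace_cellward(self):
        spec = SceneSpec(tip_fraction=0.0, n_filaments=(10, 10), seed=3)
        for tr in place_filaments(spec):
            assert tr.barbed_direction()[0] < 0

    def test_realized_composition_within_binomial_bounds(self):
        """Across several seeds, pooled tip-ward counts stay inside the
        central 99% binomial interval for p = 0.74."""
        n_tip = n_tot = 0
        for seed in range(10):
            spec = SceneSpec(tip_fraction=0.74, n_filaments=(20, 20), seed=seed)
            for tr in place_filaments(spec):
                n_tot += 1
                n_tip += tr.barbed_direction()[0] > 0
        lo = stats.binom.ppf(0.005, n_tot, 0.74)
        hi = stats.binom.ppf(0.995, n_tot, 0.74)
        assert lo <= n_tip <= hi

    def test_traces_respect_minimum_separation(self):
        spec = SceneSpec(n_filaments=(12, 12), seed=5)
        traces = place_filaments(spec)
        for i, a in enumerate(traces):
            for b in traces[i + 1:]:
                d = np.linalg.norm(a.points[:, None, :] - b.points[None, :, :],
                                   axis=2).min()
                assert d >= spec.filament_separation - 1.0

    def test_reversing_a_trace_flips_its_polarity_label(self):
        spec = SceneSpec(n_filaments=(5, 5), seed=2)
        for tr in place_filaments(spec):
            rev = tr.reversed()
            assert rev.true_polarity == -tr.true_polarity
            np.testing.assert_allclose(rev.barbed_direction(),
                                       tr.barbed_direction())

    def test_impossible_tube_raises(self):
        spec = SceneSpec(tube=TubeSpec(radius=8.0, length=30.0),
                         n_filaments=(5, 5))
        with pytest.raises(SceneError):
            place_filaments(spec)


class TestMembraneAndReceptors:
    def test_receptor_extent_matches_height_parameter(self):
        """Noise-free generator self-consistency: the rendered receptor's
        half-peak extent along the normal equals the height parameter
        within a voxel."""
        spec = SceneSpec(volume_shape=(192, 192, 128),
                         tube=TubeSpec(radius=60.0, length=100.0, clearance=2.0),
                         receptor_spec=ReceptorSpec(count=5, height=12.0),
                         seed=7)
        vol, mask, placements = place_membrane_and_receptors(spec)
        px = spec.pixel_size
        for p in placements[:3]:
            # lateral-max profile along the outward normal (the receptor is
            # bent, so a single ray would exit the head density)
            n = p["normal"]
            helper = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
            u = np.cross(n, helper); u /= np.linalg.norm(u)
            v = np.cross(n, u)
            s = np.arange(2.0, 20.0, 0.2)
            lat = np.linspace(-4.5, 4.5, 19)
            vals = np.zeros_like(s)
            for i, si in enumerate(s):
                pts = (p["position"][None, :] + si * n[None, :]
                       + lat[:, None, None] * u[None, :]
                       + lat[None, :, None] * v[None, :]).reshape(-1, 3)
                idx = np.rint(pts / px).astype(int)[:, ::-1]
                vals[i] = vol.grid[idx[:, 0], idx[:, 1], idx[:, 2]].max()
            peak = vals.max()
            extent = s[np.where(vals >= 0.5 * peak)[0][-1]]
            assert abs(extent - 12.0) <= px + 0.3

    def test_zero_receptors_leave_membrane_bare(self):
        spec = SceneSpec(volume_shape=(192, 192, 128),
                         tube=TubeSpec(radius=60.0, length=100.0, clearance=2.0),
                         receptor_spec=ReceptorSpec(count=0), seed=7)
        vol, mask, placements = place_membrane_and_receptors(spec)
        assert placements == []
        # no density beyond a couple of nm outside the outer leaflet
        nz, ny, nx = vol.grid.shape
        zz, yy = np.meshgrid(np.arange(nz), np.arange(ny), indexing="ij")
        cy = ny * spec.pixel_size / 2
        rho = np.hypot(yy * spec.pixel_size - cy,
                       zz * spec.pixel_size - spec.tube_center_z)
        outside = rho > spec.tube.radius + 4.0
        assert vol.grid[:, :, 10:80][outside[:, :, None]
                                     & np.ones((1, 1, 70), bool)].max() < 0.02

    def test_placements_respect_height_band(self):
        spec = SceneSpec(volume_shape=(192, 192, 128),
                         tube=TubeSpec(radius=60.0, length=100.0, clearance=2.0),
                         receptor_spec=ReceptorSpec(count=15), seed=9)
        _, _, placements = place_membrane_and_receptors(spec)
        assert len(placements) == 15
        for p in placements:
            assert 50.0 <= p["height_above_support"] <= 70.0

    def test_band_outside_volume_raises(self):
        spec = SceneSpec(volume_shape=(64, 64, 32),
                         tube=TubeSpec(radius=12.0, length=40.0),
                         receptor_spec=ReceptorSpec(
                             count=2, placement_band=(50.0, 70.0)))
        with pytest.raises(SceneError):
            place_membrane_and_receptors(spec)


class TestImagingModel:
    def test_full_tilt_range_is_identity(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(16, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(missing_wedge_filter(g, 90.0), g)

    def test_wedge_filter_is_idempotent(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(24, 16, 24)).astype(np.float32)
        once = missing_wedge_filter(g, 60.0)
        twice = missing_wedge_filter(once, 60.0)
        np.testing.assert_allclose(twice, once, atol=1e-5)

    def test_wedge_filter_is_linear(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(16, 8, 16)).astype(np.float32)
        b = rng.normal(size=(16, 8, 16)).astype(np.float32)
        lhs = missing_wedge_filter(a + 2 * b, 60.0)
        rhs = missing_wedge_filter(a, 60.0) + 2 * missing_wedge_filter(b, 60.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_wedge_never_increases_fourier_power(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=(16, 16, 16)).astype(np.float32)
        for tilt in (30.0, 60.0, 80.0):
            out = missing_wedge_filter(g, tilt)
            assert np.sum(out.astype(np.float64) ** 2) <= np.sum(
                g.astype(np.float64) ** 2) + 1e-6

    def test_zeroed_fraction_matches_per_voxel_angle_oracle(self):
        """The number of zeroed Fourier coefficients equals a brute-force
        per-voxel test of the wedge angle condition."""
        shape = (20, 6, 24)
        rng = np.random.default_rng(4)
        g = rng.normal(size=shape)
        tilt = 60.0
        spec_in = np.fft.fftn(g)
        # float32 round-off leaves ~1e-7-relative residue on zeroed coeffs
        spec_out = np.fft.fftn(missing_wedge_filter(g, tilt))
        zeroed = np.abs(spec_out) < 1e-3 * np.abs(spec_in).max()
        # brute force: |kz| > tan(tilt) |kx| is unmeasured
        kz = np.fft.fftfreq(shape[0])
        kx = np.fft.fftfreq(shape[2])
        count = 0
        for iz, fz in enumerate(kz):
            for ix, fx in enumerate(kx):
                if abs(fz) > math.tan(math.radians(tilt)) * abs(fx) + 1e-12:
                    count += shape[1]
        assert zeroed.sum() == count

    def test_invalid_tilt_rejected(self):
        g = np.zeros((8, 8, 8), dtype=np.float32)
        with pytest.raises(SceneError):
            missing_wedge_filter(g, 0.0)
        with pytest.raises(SceneError):
            missing_wedge_filter(g, 91.0)


class TestSceneDeterminism:
    def test_fixed_seed_reproduces_scene_bit_for_bit(self, small_scene_spec):
        t1, g1 = generate_scene(small_scene_spec)
        t2, g2 = generate_scene(small_scene_spec)
        np.testing.assert_array_equal(t1.grid, t2.grid)
        assert len(g1.traces) == len(g2.traces)
        for a, b in zip(g1.traces, g2.traces):
            np.testing.assert_array_equal(a.points, b.points)
            assert a.true_polarity == b.true_polarity

    def test_ground_truth_backprojects_into_density(self, small_scene_spec):
        """Noise-free scenes carry density at every ground-truth filament
        point and receptor placement."""
        spec = replace(small_scene_spec, noise_sigma=0.0, tilt_range=90.0)
        tomo, gt = generate_scene(spec)
        px = tomo.pixel_size
        for tr in gt.traces:
            for p in tr.points[1:-1]:
                iz, iy, ix = np.rint(p[::-1] / px).astype(int)
                patch = tomo.grid[iz - 3:iz + 4, iy - 3:iy + 4, ix - 3:ix + 4]
                assert patch.max() > 0.1
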