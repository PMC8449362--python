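"""Membrane normals, receptor picking, averaging, classification, height
measurement, rigid fitting and spatial statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pseudopodtomo.receptors import (ReceptorError, SubvolumeStack,
                                     align_average, classify_3d,
                                     density_extent_above, estimate_normals,
                                     extract_stack, measure_height,
                                     pick_densities, render_pseudo_atoms,
                                     rigid_fit_score, spatial_randomness_test)
from pseudopodtomo.scene import generate_scene
from pseudopodtomo.volume import TomogramVolume


class TestEstimateNormals:
    def test_flat_plane_normals_consistent_along_z(self):
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[15:17] = True
        model = estimate_normals(mask, 1.0)
        nz = model.outward_normals[:, 2]
        assert np.all(np.abs(nz) > 0.99)
        assert len(set(np.sign(nz))) == 1  # one consistent orientation

    def test_sphere_normals_radial_and_outward(self):
        zz, yy, xx = np.meshgrid(*[np.arange(48.0)] * 3, indexing="ij")
        r = np.sqrt((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2)
        mask = np.abs(r - 14.0) < 1.5
        model = estimate_normals(mask, 1.0)
        radial = model.surface_points - 24.0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cos = np.sum(model.outward_normals * radial, axis=1)
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert np.mean(ang) < 5.0
        assert np.mean(cos > 0) > 0.99  # outward, not inward

    def test_all_normals_unit_length(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[10:12] = True
        model = estimate_normals(mask, 1.0)
        np.testing.assert_allclose(np.linalg.norm(model.outward_normals, axis=1),
                                   1.0, atol=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ReceptorError):
            estimate_normals(np.zeros((8, 8, 8), dtype=bool), 1.0)


@pytest.fixture(scope="module")
def receptor_scene_analysis(small_receptor_scene, receptor_config):
    from pseudopodtomo.pipeline import receptor_scene_analysis as rsa
    spec, (tomo, gt) = small_receptor_scene
    return spec, tomo, gt, rsa(tomo, gt, receptor_config)


class TestPickDensities:
    def test_out_of_band_receptor_rejected_with_height_reason(
            self, small_receptor_scene, receptor_config):
        """A pick 30 nm above the support falls outside the 50-70 nm
        analysis band and must carry the 'height' rejection reason."""
        spec, (tomo, gt) = small_receptor_scene
        membrane = estimate_normals(gt.membrane_mask, tomo.pixel_size,
                                    support_z=gt.support_z)
        picks = pick_densities(tomo, membrane, height_band=(50.0, 70.0))
        low = [p for p in picks if p.height_above_support < 45.0]
        assert low, "scene should offer candidates below the band"
        assert all((not p.kept) and p.reason == "height" for p in low)

    def test_every_rejection_has_exactly_one_reason(self, receptor_scene_analysis):
        _, _, _, res = receptor_scene_analysis
        picks = res["picks"]
        for p in picks:
            if p.kept:
                assert p.reason is None
            else:
                assert p.reason in ("height", "tilt", "proximity")
        kept = sum(p.kept for p in picks)
        rejected = sum(not p.kept for p in picks)
        assert kept + rejected == len(picks)

    def test_in_band_receptors_recovered(self, receptor_scene_analysis):
        """At the default noise level at least 90% of kept picks land
        within 5 nm of a true receptor head."""
        _, _, gt, res = receptor_scene_analysis
        kept = [p for p in res["picks"] if p.kept]
        heads = np.array([p["head_position"] for p in gt.receptor_placements])
        matched = sum(np.linalg.norm(heads - p.position, axis=1).min() <= 5.0
                      for p in kept)
        assert matched / len(kept) >= 0.9

    def test_receptor_free_scene_has_no_excess_picks(
            self, small_receptor_scene, receptor_config):
        """A receptor-free membrane yields no more picks than the
        noise-only false-positive level measured on the same scene."""
        from pseudopodtomo.scene import ReceptorSpec
        spec, _ = small_receptor_scene
        bare_spec = replace(spec, receptor_spec=ReceptorSpec(count=0), seed=33)
        tomo, gt = generate_scene(bare_spec)
        membrane = estimate_normals(gt.membrane_mask, tomo.pixel_size,
                                    support_z=gt.support_z)
        picks = pick_densities(tomo, membrane)
        kept = [p for p in picks if p.kept]
        # noise-only calibration: same geometry, different noise seed
        tomo2, gt2 = generate_scene(replace(bare_spec, seed=44))
        membrane2 = estimate_normals(gt2.membrane_mask, tomo2.pixel_size,
                                     support_z=gt2.support_z)
        noise_only = [p for p in pick_densities(tomo2, membrane2) if p.kept]
        assert len(kept) <= len(noise_only) + 3

    def test_ill_ordered_bands_rejected(self, receptor_scene_analysis):
        spec, tomo, gt, res = receptor_scene_analysis
        with pytest.raises(ValueError):
            pick_densities(tomo, res["membrane"], attach_band=(10.0, 2.0))


class TestAlignAverage:
    def test_single_box_with_z_normal_is_identity(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(48, 48, 48)).astype(np.float32)
        tomo = TomogramVolume(g, 1.0)
        from pseudopodtomo.receptors import ReceptorPick
        pick = ReceptorPick(position=np.array([24.0, 24.0, 26.0]),
                            surface_point=np.array([24.0, 24.0, 24.0]),
                            normal=np.array([0.0, 0.0, 1.0]),
                            height_above_support=24.0, normal_tilt=90.0,
                            density=1.0)
        stack = extract_stack(tomo, [pick], box_edge=16, center_inset_nm=0.0)
        model = align_average(stack)
        idx = np.rint([24.0, 24.0, 24.0]).astype(int)
        sub = g[idx[2] - 8:idx[2] + 8, idx[1] - 8:idx[1] + 8, idx[0] - 8:idx[0] + 8]
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(model[core], sub[core], atol=1e-3)

    def test_averaging_gain_over_single_boxes(self, receptor_scene_analysis):
        """The initial model correlates with the selected class average
        better than a typical single box does (noise averaging)."""
        _, _, _, res = receptor_scene_analysis
        sel = res["class_volumes"][res["selected_class"]]
        model = res["initial_model"]

        def ncc(a, b):
            a = a - a.mean(); b = b - b.mean()
            return float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b)))

        singles = [ncc(b, sel) for b in res["stack"].boxes[:10]]
        assert ncc(model, sel) > max(singles)

    def test_empty_stack_rejected(self):
        stack = SubvolumeStack([], [], 16, 1.0, 7.5)
        with pytest.raises(ReceptorError):
            align_average(stack)


class TestClassify3D:
    def _stack(self, n_a=20, n_b=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = np.zeros((16, 16, 16)); a[8:12, 6:10, 6:10] = 1.0
        b = np.zeros((16, 16, 16)); b[4:6, 4:12, 4:12] = 1.0
        boxes = ([a + rng.normal(0, noise, a.shape) for _ in range(n_a)]
                 + [b + rng.normal(0, noise, b.shape) for _ in range(n_b)])
        return SubvolumeStack(boxes, [np.eye(3)] * (n_a + n_b), 16, 1.0, 7.5)

    def test_noise_free_mixture_separates_perfectly(self):
        stack = self._stack()
        labels, vols, sel = classify_3d(stack, k=2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_label_permutation_invariance(self):
        """Different seeds may permute class ids, but the induced
        partition is identical."""
        stack = self._stack(noise=0.2)
        l1, _, _ = classify_3d(stack, k=2, seed=0)
        l2, _, _ = classify_3d(stack, k=2, seed=99)
        same = (l1[:, None] == l1[None, :])
        same2 = (l2[:, None] == l2[None, :])
        np.testing.assert_array_equal(same, same2)

    def test_separation_at_noise_matches_template_oracle(self):
        """Classification accuracy at moderate noise is at least that of
        thresholding each box's NCC against the two noise-free templates."""
        noise = 0.8
        stack = self._stack(noise=noise, seed=5)
        truth = np.array([0] * 20 + [1] * 20)
        labels, _, _ = classify_3d(stack, k=2, seed=1)
        acc = max(np.mean(labels == truth), np.mean(labels != truth))
        a = np.zeros((16, 16, 16)); a[8:12, 6:10, 6:10] = 1.0
        b = np.zeros((16, 16, 16)); b[4:6, 4:12, 4:12] = 1.0

        def ncc(x, t):
            x = x - x.mean(); t = t - t.mean()
            return (x * t).sum() / (np.linalg.norm(x) * np.linalg.norm(t))

        oracle = np.array([0 if ncc(bx, a) > ncc(bx, b) else 1
                           for bx in stack.boxes])
        oracle_acc = max(np.mean(oracle == truth), np.mean(oracle != truth))
        assert acc >= oracle_acc - 0.05

    def test_k_exceeding_stack_rejected(self):
        stack = self._stack(n_a=1, n_b=1)
        with pytest.raises(ReceptorError):
            classify_3d(stack, k=5)


class TestMeasureHeight:
    def _membrane_box(self, receptor_height=None, edge=32, px=1.1):
        g = np.zeros((edge,) * 3, dtype=np.float32)
        zc = (edge - 1) / 2
        z = np.arange(edge)
        g += np.exp(-0.5 * ((z - zc) / 0.9) ** 2)[:, None, None]
        g += np.exp(-0.5 * ((z - zc + 5 / px) / 0.9) ** 2)[:, None, None]
        if receptor_height is not None:
            for h_nm, sig in [(receptor_height * 0.3, 1.5),
                              (receptor_height - 2.36, 2.0)]:
                dz = h_nm / px
                g += 1.2 * np.exp(-0.5 * (((z - zc - dz) / (sig / px)) ** 2)
                                  )[:, None, None] \
                    * np.exp(-0.5 * (((np.arange(edge) - zc) / 3) ** 2))[None, None, :] \
                    * np.exp(-0.5 * (((np.arange(edge) - zc) / 3) ** 2))[None, :, None]
        return g, zc

    def test_bare_membrane_measures_zero_flagged(self):
        g, zc = self._membrane_box(None)
        h, flagged = measure_height(g, zc, 1.1)
        assert h == 0.0 and flagged

    def test_synthetic_receptor_height_recovered(self):
        g, zc = self._membrane_box(12.0)
        h, flagged = measure_height(g, zc, 1.1)
        assert not flagged
        assert abs(h - 12.0) <= 1.5

    def test_height_monotone_in_threshold_level(self):
        g, zc = self._membrane_box(12.0)
        heights = [measure_height(g, zc, 1.1, level=lv)[0]
                   for lv in (0.3, 0.4, 0.5, 0.6, 0.7)]
        assert all(a >= b - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_pipeline_recovers_generator_height(self, receptor_scene_analysis):
        """End-to-end pick -> average -> classify -> measure returns the
        12 nm generator height within 1.5 nm on one scene."""
        _, _, _, res = receptor_scene_analysis
        assert not res["height_flagged"]
        assert abs(res["height_nm"] - 12.0) <= 1.5


class TestRigidFit:
    def _coords(self):
        rng = np.random.default_rng(1)
        return rng.uniform(8, 18, size=(30, 3))

    def test_self_fit_scores_unity_at_identity(self):
        coords = self._coords()
        vol = render_pseudo_atoms(coords, None, (24, 24, 24), 1.0, 2.0)
        tf, score = rigid_fit_score(vol, coords, 2.0, 1.0,
                                    rotations=[Rotation.identity()],
                                    refine=True)
        assert score > 0.97
        np.testing.assert_allclose(tf["centroid_nm"], coords.mean(axis=0),
                                   atol=0.5)

    def test_known_translation_recovered(self):
        """A map shifted by a known vector is fitted with the centroid
        recovered within half a voxel."""
        coords = self._coords()
        shift = np.array([2.0, -3.0, 1.0])
        vol = render_pseudo_atoms(coords + shift, None, (24, 24, 24), 1.0, 2.0)
        tf, score = rigid_fit_score(vol, coords, 2.0, 1.0,
                                    rotations=[Rotation.identity()],
                                    refine=True)
        assert score > 0.97
        np.testing.assert_allclose(tf["centroid_nm"],
                                   coords.mean(axis=0) + shift, atol=0.5)

    def test_coarse_rotation_search_finds_a_rotated_copy(self):
        coords = self._coords()
        true_rot = Rotation.from_euler("zyz", [40, 25, 10], degrees=True)
        centroid = coords.mean(axis=0)
        vol = render_pseudo_atoms(true_rot.apply(coords - centroid) + centroid,
                                  None, (24, 24, 24), 1.0, 2.5)
        tf, score = rigid_fit_score(vol, coords, 2.5, 1.0, rot_step_deg=30.0,
                                    refine=True)
        assert score > 0.9


class TestSpatialRandomness:
    def _surface(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        # a cylinder band, similar to the analysed membrane region
        theta = rng.uniform(0, np.pi / 3, n)
        x = rng.uniform(0, 180, n)
        return np.column_stack([x, 60 * np.cos(theta), 60 * np.sin(theta)])

    def test_uniform_picks_give_calibrated_p_values(self):
        """Under complete spatial randomness the Monte-Carlo p-values are
        approximately uniform (Kolmogorov distance < 0.15 over 100 runs)."""
        surf = self._surface()
        rng = np.random.default_rng(1)
        ps = []
        for i in range(100):
            picks = surf[rng.choice(len(surf), 20, replace=False)]
            out = spatial_randomness_test(picks, surf, n_mc=99, seed=1000 + i)
            ps.append(out["p_value"])
        ps = np.sort(ps)
        grid = (np.arange(1, 101)) / 100
        ks = np.max(np.abs(ps - grid))
        assert ks < 0.15

    def test_clustered_picks_detected(self):
        surf = self._surface()
        center = surf[100]
        d = np.linalg.norm(surf - center, axis=1)
        cluster = surf[np.argsort(d)[:15]]  # one tight patch
        out = spatial_randomness_test(cluster, surf, n_mc=999, seed=5)
        assert out["p_value"] <= 0.01

    def test_zero_monte_carlo_draws_rejected(self):
        surf = self._surface(50)
        with pytest.raises(ValueError):
            spatial_randomness_test(surf[:10], surf, n_mc=0)

    def test_insufficient_picks_rejected(self):
        surf = self._surface(50)
        with pytest.raises(ReceptorError):
            spatial_randomness_test(surf[:4], surf, n_mc=99)
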