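"""Synthetic phantom: determinism, lesion semantics, speckle statistics,
misalignment bookkeeping."""

import numpy as np
import pytest

from ischemap import lsci, phantom, registration, tps
from ischemap.errors import ValidationError


def healthy_tissue_mask(scene):
    return (scene.tissue_mask & ~scene.lesion_mask & ~scene.transition_mask)


class TestGenerateScene:
    def test_seeded_determinism(self, small_scene):
        again = phantom.generate_scene(small_scene.config)
        assert np.array_equal(again.rgb, small_scene.rgb)
        assert np.array_equal(again.speckle.frames, small_scene.speckle.frames)
        assert np.array_equal(again.warp_truth, small_scene.warp_truth)
        assert np.array_equal(again.landmarks.lsci_points,
                              small_scene.landmarks.lsci_points)

    def test_landmark_count_in_protocol_range(self):
        for seed in range(5):
            cfg = phantom.PhantomConfig(size=(64, 64), n_frames=4, seed=seed)
            scene = phantom.generate_scene(cfg)
            assert 7 <= len(scene.landmarks) <= 9

    def test_lesion_flow_below_background(self, small_scene):
        inside = small_scene.flow_map[small_scene.lesion_mask].mean()
        outside = small_scene.flow_map[healthy_tissue_mask(small_scene)].mean()
        assert inside < outside

    def test_high_severity_core_below_60pct_of_background(self):
        for sev in (0.5, 0.8):
            cfg = phantom.PhantomConfig(
                size=(64, 64), n_frames=4,
                lesion=phantom.LesionSpec(radius=10, severity=sev), seed=1)
            sc = phantom.generate_scene(cfg)
            core = sc.flow_map[sc.lesion_mask].mean()
            bg = sc.flow_map[healthy_tissue_mask(sc)].mean()
            assert core < 0.6 * bg

    def test_null_lesion_leaves_flow_at_baseline(self):
        base = phantom.PhantomConfig(size=(64, 64), n_frames=4, seed=5,
                                     lesion=phantom.LesionSpec(radius=0))
        with_null = phantom.PhantomConfig(
            size=(64, 64), n_frames=4, seed=5,
            lesion=phantom.LesionSpec(radius=10, severity=0.0))
        assert np.array_equal(phantom.generate_scene(base).flow_map,
                              phantom.generate_scene(with_null).flow_map)

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValidationError):
            phantom.PhantomConfig(size=(64, 64),
                                  lesion=phantom.LesionSpec(radius=200))

    def test_vessels_darker_contrast_than_parenchyma(self, aligned_scene):
        sc = aligned_scene
        mean_frame = sc.speckle.frames.mean(axis=0)
        k = lsci.compute_spatial_contrast(mean_frame, 5).values
        vessels = sc.flow_map > 3.0
        parench = healthy_tissue_mask(sc) & (sc.flow_map < 1.8) \
            & (sc.flow_map > 0)
        assert k[vessels].mean() < k[parench].mean()


class TestApplyIschemia:
    def test_full_occlusion_zero_core(self):
        flow = np.ones((32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        out = phantom.apply_ischemia(flow, mask, 1.0, 0.0)
        assert np.allclose(out[mask], 0.0)
        assert np.allclose(out[~mask], 1.0)

    def test_zero_severity_identity(self, rng):
        flow = rng.random((16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:8] = True
        assert np.array_equal(phantom.apply_ischemia(flow, mask, 0.0, 3.0),
                              flow)

    def test_monotone_profile_along_ray(self):
        flow = np.ones((64, 64))
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 32) ** 2 + (xx - 32) ** 2 <= 64] = True
        out = phantom.apply_ischemia(flow, mask, 0.9, 6.0)
        profile = out[32, 32:]          # ray from core center outward
        assert np.all(np.diff(profile) >= -1e-12)

    def test_negative_width_rejected(self):
        with pytest.raises(ValidationError):
            phantom.apply_ischemia(np.ones((8, 8)),
                                   np.zeros((8, 8), dtype=bool), 0.5, -1.0)


class TestSynthesizeSpeckle:
    def test_temporal_contrast_matches_target(self):
        flow = np.full((24, 24), 2.0)
        stack = phantom.synthesize_speckle(flow, 600, 0.0, seed=3)
        k_target = 1.0 / np.sqrt(1.0 + phantom.FLOW_COUPLING * 2.0)
        k = lsci.compute_temporal_contrast(lsci.SpeckleStack(stack.frames),
                                           600)
        mc_se = k_target / np.sqrt(2 * 600)
        assert abs(k.values.mean() - k_target) < 3 * mc_se

    def test_zero_flow_fully_developed(self):
        stack = phantom.synthesize_speckle(np.zeros((16, 16)), 800, 0.0, seed=1)
        k = lsci.compute_temporal_contrast(lsci.SpeckleStack(stack.frames), 800)
        assert abs(k.values.mean() - 1.0) < 0.02

    def test_global_motion_bounded_by_ten_percent(self):
        flow = np.ones((64, 64))
        stack = phantom.synthesize_speckle(flow, 128, 0.10, seed=9)
        means = stack.frames.mean(axis=(1, 2))
        med = np.median(means)
        # ±10% modulation plus 3 standard errors of the 64x64 mean estimate
        assert np.all(np.abs(means - med) / med <= 0.10 + 0.02)

    def test_invalid_frame_count_rejected(self):
        with pytest.raises(ValidationError):
            phantom.synthesize_speckle(np.ones((8, 8)), 0, 0.0, seed=0)


class TestMisalign:
    def test_zero_magnitude_identity(self, aligned_scene):
        out = phantom.misalign(aligned_scene, 0.0, seed=1)
        assert np.allclose(out.warp_truth, 0.0)
        assert np.array_equal(out.lsci, aligned_scene.lsci)
        assert np.array_equal(out.landmarks.lsci_points,
                              out.landmarks.rgb_points)

    def test_seeded_reproducibility(self, aligned_scene):
        a = phantom.misalign(aligned_scene, 4.0, seed=7)
        b = phantom.misalign(aligned_scene, 4.0, seed=7)
        assert np.array_equal(a.warp_truth, b.warp_truth)
        assert np.array_equal(a.lsci, b.lsci)

    def test_warp_truth_realigns_flow_map(self, aligned_scene):
        mis = phantom.misalign(aligned_scene, 4.0, seed=3)
        warped_flow = phantom._warp_scalar(
            aligned_scene.flow_map,
            tps.random_tps_field((64, 64), 4.0, np.random.default_rng(3),
                                 grid=aligned_scene.config.warp_grid))
        back = registration.warp(warped_flow, mis.warp_truth)
        dyn = aligned_scene.flow_map.max() - aligned_scene.flow_map.min()
        mae = np.abs(back - aligned_scene.flow_map).mean() / dyn
        assert mae < 0.02

    def test_landmark_transport_consistent_with_truth_field(self, small_scene):
        err = registration.landmark_error(small_scene.landmarks,
                                          small_scene.warp_truth)
        assert err["overall"] < 0.05

    def test_landmark_displacement_bounded(self, small_scene):
        disp = np.linalg.norm(small_scene.landmarks.lsci_points
                              - small_scene.landmarks.rgb_points, axis=1)
        # TPS interpolation of control offsets <= magnitude can mildly
        # overshoot between control points
        assert disp.max() <= small_scene.config.warp_magnitude * 1.5


class TestLandmarkCSV:
    def test_round_trip(self, small_scene, tmp_path):
        path = tmp_path / "lm.csv"
        small_scene.landmarks.save_csv(path)
        back = phantom.LandmarkSet.load_csv(path)
        assert back.classes == small_scene.landmarks.classes
        assert np.allclose(back.rgb_points, small_scene.landmarks.rgb_points,
                           atol=1e-3)
        assert np.allclose(back.lsci_points,
                           small_scene.landmarks.lsci_points, atol=1e-3)


def test_scene_directory_export(small_scene, tmp_path):
    phantom.save_scene(small_scene, tmp_path / "scene")
    for name in ("rgb.png", "lsci.tiff", "flow.tiff", "lesion_mask.png",
                 "landmarks.csv", "warp.npz"):
        assert (tmp_path / "scene" / name).exists()
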