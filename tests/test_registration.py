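"""Registration primitives: warping, bilateral weights, loss terms,
landmark transport and the deformation heatmap."""

import numpy as np
import pytest

from ischemap import registration as R
from ischemap.errors import DimensionError, ValidationError
from ischemap.phantom import LandmarkSet


class TestWarp:
    def test_zero_field_identity(self, rng):
        img = rng.random((16, 16))
        out = R.warp(img, np.zeros((2, 16, 16)))
        assert np.allclose(out, img, atol=1e-12)

    def test_integer_shift_exact(self, rng):
        img = rng.random((12, 12))
        field = np.zeros((2, 12, 12))
        field[1] = 3.0                       # Δcol = +3: sample source right
        out = R.warp(img, field)
        assert np.allclose(out[:, :9], img[:, 3:], atol=1e-12)

    def test_half_pixel_shift_on_linear_ramp(self):
        ramp = np.tile(np.arange(10, dtype=float), (10, 1))
        field = np.zeros((2, 10, 10))
        field[1] = 0.5
        out = R.warp(ramp, field)
        # interior: values advance by half the ramp step
        assert np.allclose(out[:, :9], ramp[:, :9] + 0.5, atol=1e-12)

    def test_multichannel_and_shape_mismatch(self, rng):
        img = rng.random((8, 8, 3))
        out = R.warp(img, np.zeros((2, 8, 8)))
        assert out.shape == (8, 8, 3)
        with pytest.raises(DimensionError):
            R.warp(img, np.zeros((2, 6, 6)))


class TestBilateralWeights:
    def test_constant_guide_uniform_weights(self):
        w = R.bilateral_weights(np.full((8, 8), 0.3), 2.0, 0.1)
        # interior pixel: all 9 neighbours present, range term = 1
        center = w[4, 4]
        spatial = np.exp(-np.array([[2, 1, 2], [1, 0, 1], [2, 1, 2]])
                         / (2 * 4.0))
        assert np.allclose(center, spatial / spatial.sum(), atol=1e-12)

    def test_normalized_per_pixel(self, rng):
        w = R.bilateral_weights(rng.random((10, 10)), 2.0, 0.1)
        assert np.allclose(w.sum(axis=(2, 3)), 1.0, atol=1e-12)

    def test_symmetry_of_unnormalized_kernel(self, rng):
        guide = rng.random((6, 6))
        sp, sr = 2.0, 0.1
        for (u, v, du, dv) in [((2, 2), (2, 3), (0, 1), (0, -1)),
                               ((1, 1), (2, 2), (1, 1), (-1, -1))]:
            b_uv = np.exp(-(du[0] ** 2 + du[1] ** 2) / (2 * sp ** 2)) * np.exp(
                -(guide[u] - guide[v]) ** 2 / (2 * sr ** 2))
            b_vu = np.exp(-(dv[0] ** 2 + dv[1] ** 2) / (2 * sp ** 2)) * np.exp(
                -(guide[v] - guide[u]) ** 2 / (2 * sr ** 2))
            assert b_uv == pytest.approx(b_vu, abs=1e-15)

    def test_weight_decreases_with_intensity_gap(self):
        guide = np.zeros((5, 5))
        guide[2, 3] = 0.2
        w_small = R.bilateral_weights(guide, 2.0, 0.1)[2, 2, 1, 2]
        guide[2, 3] = 0.8
        w_large = R.bilateral_weights(guide, 2.0, 0.1)[2, 2, 1, 2]
        assert w_large < w_small

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            R.bilateral_weights(np.zeros((4, 4)), 0.0, 0.1)


class TestLossSmooth:
    def test_constant_field_zero(self):
        field = np.full((2, 8, 8), 2.5)
        w = R.bilateral_weights(np.zeros((8, 8)), 2.0, 0.1)
        assert R.loss_smooth(field, w) == pytest.approx(0.0, abs=1e-5)

    def test_translation_invariance(self, rng):
        field = rng.normal(size=(2, 8, 8))
        w = R.bilateral_weights(rng.random((8, 8)), 2.0, 0.1)
        a = R.loss_smooth(field, w)
        b = R.loss_smooth(field + 7.0, w)
        assert a == pytest.approx(b, rel=1e-5)

    def test_single_spike_matches_double_sum_oracle(self):
        h = w = 6
        field = np.zeros((2, h, w))
        field[0, 3, 3] = 2.0                  # spike of magnitude m
        guide = np.zeros((h, w))
        weights = R.bilateral_weights(guide, 2.0, 0.1)
        # brute-force: sum over pixels v and 8-neighbours u of
        # B(u,v)·||phi(u)-phi(v)|| with normalized-coordinate scaling
        scale = 2.0 / h
        total = 0.0
        for i in range(h):
            for j in range(w):
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if not (0 <= ii < h and 0 <= jj < w):
                            continue
                        diff = (field[:, ii, jj] - field[:, i, j]) * scale
                        total += weights[i, j, di + 1, dj + 1] * np.linalg.norm(diff)
        assert R.loss_smooth(field, weights) == pytest.approx(
            total / (h * w), rel=1e-4)


class TestLossAnti:
    def test_identity_case_zero(self, rng):
        rgb = rng.random((6, 6, 3))
        lsci = rng.random((6, 6))
        assert R.loss_anti(rgb, rgb, lsci, lsci) == 0.0

    def test_constant_offset(self, rng):
        rgb = rng.random((6, 6, 3))
        lsci = rng.random((6, 6))
        assert R.loss_anti(rgb, rgb, lsci + 0.1, lsci) == pytest.approx(0.1)

    def test_negative_weighting_rewards_departure_from_identity(self, rng):
        rgb = rng.random((4, 4, 3))
        lsci = rng.random((4, 4))
        lam_a = -2.0
        near = lam_a * R.loss_anti(rgb + 0.01, rgb, lsci, lsci)
        far = lam_a * R.loss_anti(rgb + 0.3, rgb, lsci, lsci)
        assert far < near                     # larger departure lowers total


class TestLandmarkError:
    def test_coincident_points_zero_field(self):
        pts = np.array([[3.0, 4.0], [7.0, 2.0]])
        lm = LandmarkSet(["object", "interior"], pts.copy(), pts.copy())
        err = R.landmark_error(lm, np.zeros((2, 16, 16)))
        assert err["overall"] == pytest.approx(0.0)

    def test_three_four_five_triangle(self):
        lm = LandmarkSet(["object"], np.array([[8.0, 9.0]]),
                         np.array([[5.0, 5.0]]))
        err = R.landmark_error(lm, np.zeros((2, 16, 16)))
        assert err["overall"] == pytest.approx(5.0)

    def test_exact_constant_field_corrects_offset(self):
        # LSCI feature at (5,5); its RGB partner sits at (8,9).  A constant
        # field (-3,-4) carries the LSCI content onto the RGB frame exactly.
        lm = LandmarkSet(["object"], np.array([[8.0, 9.0]]),
                         np.array([[5.0, 5.0]]))
        field = np.zeros((2, 16, 16))
        field[0], field[1] = -3.0, -4.0
        err = R.landmark_error(lm, field)
        assert err["overall"] == pytest.approx(0.0, abs=1e-9)

    def test_per_class_breakdown(self):
        pts = np.array([[2.0, 2.0], [4.0, 4.0], [6.0, 6.0]])
        lm = LandmarkSet(["object", "interior", "background"],
                         pts + [0.0, 1.0], pts.copy())
        err = R.landmark_error(lm, np.zeros((2, 10, 10)))
        assert set(err) == {"overall", "object", "interior", "background"}
        assert err["object"] == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        lm = LandmarkSet([], np.zeros((0, 2)), np.zeros((0, 2)))
        with pytest.raises(ValidationError):
            R.landmark_error(lm, np.zeros((2, 8, 8)))


class TestDeformationHeatmap:
    def test_zero_field_black(self):
        assert np.all(R.deformation_heatmap(np.zeros((2, 8, 8))) == 0.0)

    def test_hot_pixel_is_brightest(self):
        field = np.zeros((2, 8, 8))
        field[0, 3, 5] = 4.0
        hm = R.deformation_heatmap(field)
        assert hm[3, 5] == 1.0 and hm.max() == 1.0

    def test_magnitudes_match_hand_computed(self):
        field = np.zeros((2, 3, 3))
        field[0] = [[3, 0, 0], [0, 1, 0], [0, 0, 0]]
        field[1] = [[4, 0, 0], [0, 1, 0], [0, 0, 2]]
        hm = R.deformation_heatmap(field)
        expected = np.sqrt(field[0] ** 2 + field[1] ** 2)
        assert np.allclose(hm, expected / 5.0, atol=1e-12)


class TestDeformationFieldType:
    def test_rejects_bad_shape_and_nonfinite(self):
        with pytest.raises(DimensionError):
            R.DeformationField(np.zeros((3, 4, 4)))
        bad = np.zeros((2, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            R.DeformationField(bad)


class TestTrainingBookkeeping:
    def test_objective_assembly_and_history(self, small_scene, aligned_scene):
        """One float64 epoch: recorded total equals the λ-weighted sum of
        the recorded terms, smoothness is nonnegative, history lengths
        match the epochs run."""
        from ischemap import preprocessing
        from ischemap.nn.autograd import default_dtype

        pairs = []
        for sc in (small_scene, aligned_scene):
            pairs.append((preprocessing.normalize(sc.rgb).values,
                          preprocessing.normalize(-sc.lsci).values,
                          sc.landmarks))
        weights = R.RegistrationLossWeights()
        with default_dtype(np.float64):
            bundle = R.train_registration(
                pairs, weights,
                R.RegistrationTrainConfig(epochs=2, early_stopping=False,
                                          seed=0, gen_channels=[4, 8],
                                          disc_channels=[4, 8],
                                          reg_channels=[4, 8],
                                          n_res_blocks=1))
        h = bundle.history
        assert all(len(h[k]) == 2 for k in
                   ("d_loss", "g_adv", "recon", "smooth", "anti", "total"))
        assert all(s >= 0 for s in h["smooth"])
        for e in range(2):
            assembled = (h["g_adv"][e] + weights.lambda_r * h["recon"][e]
                         + weights.lambda_s * h["smooth"][e]
                         + weights.lambda_a * h["anti"][e])
            assert h["total"][e] == pytest.approx(assembled, abs=1e-6)

    def test_huge_smoothness_weight_freezes_motion(self):
        """An extreme λS pins the deformation field near zero relative to
        the default weighting (smoothness vetoes movement)."""
        from ischemap import phantom, preprocessing

        pairs = []
        for seed in (31, 32, 33, 34):
            sc = phantom.generate_scene(phantom.PhantomConfig(
                size=(64, 64), n_frames=32, warp_magnitude=6.0,
                lesion=phantom.LesionSpec(radius=0), seed=seed))
            pairs.append((preprocessing.normalize(sc.rgb).values,
                          preprocessing.normalize(-sc.lsci).values,
                          sc.landmarks))
        cfg = dict(epochs=25, early_stopping=False, seed=1,
                   gen_channels=[8, 16], disc_channels=[8, 16],
                   warmup_epochs=5)
        mags = {}
        for lam_s in (130.0, 130000.0):
            bundle = R.train_registration(
                pairs, R.RegistrationLossWeights(lambda_s=lam_s),
                R.RegistrationTrainConfig(**cfg))
            fields = [R.register_pair(bundle, p[0], p[1])[1].values
                      for p in pairs]
            mags[lam_s] = np.mean([np.abs(f).mean() for f in fields])
        assert mags[130000.0] < mags[130.0]
        assert mags[130000.0] < 0.5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            R.train_registration([(np.zeros((64, 64, 3)),
                                   np.zeros((64, 64)), None)])

    def test_untrained_bundle_cannot_register(self, rng):
        from ischemap.errors import StateError
        from ischemap.networks import ModelBundle

        bundle = ModelBundle(models={}, specs={})
        with pytest.raises(StateError):
            R.register_pair(bundle, rng.random((64, 64, 3)),
                            rng.random((64, 64)))
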