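"""Segmentation metrics and transition-zone ground truth vs brute force."""

import numpy as np
import pytest

from ischemap import evaluation as E
from ischemap.errors import ValidationError


def brute_force_metrics(pred, gt_abnormal):
    tp = np.sum(pred & gt_abnormal)
    tn = np.sum(~pred & ~gt_abnormal)
    fp = np.sum(pred & ~gt_abnormal)
    fn = np.sum(~pred & gt_abnormal)
    return dict(
        ac=(tp + tn) / (tp + tn + fp + fn),
        dc=2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 0.0,
        se=tp / (tp + fn) if tp + fn else 0.0,
        sp=tn / (tn + fp) if tn + fp else 0.0,
        pe=tp / (tp + fp) if tp + fp else 0.0,
    )


def mann_whitney_auc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        gt = np.zeros((10, 10), dtype=np.int8)
        gt[2:5] = E.LABEL_ABNORMAL
        c = E.confusion(gt == E.LABEL_ABNORMAL, gt)
        assert c.fp == 0 and c.fn == 0 and c.total == 100

    def test_total_disagreement(self):
        gt = np.zeros((6, 6), dtype=np.int8)
        gt[:3] = E.LABEL_ABNORMAL
        c = E.confusion(gt != E.LABEL_ABNORMAL, gt)
        assert c.tp == 0 and c.tn == 0

    def test_buffer_excluded_from_partition(self):
        gt = np.zeros((8, 8), dtype=np.int8)
        gt[0:2] = E.LABEL_ABNORMAL
        gt[2:4] = E.LABEL_BUFFER
        c = E.confusion(np.ones((8, 8), dtype=bool), gt)
        assert c.total == 64 - 16

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            E.confusion(np.ones((4, 4), dtype=bool),
                        np.zeros((4, 4), dtype=np.int8), (2, 2, 0, 4))


class TestMetrics:
    def test_worked_example(self):
        rep = E.metrics(E.ConfusionCounts(tp=8, fp=2, fn=2, tn=88))
        assert rep.accuracy == pytest.approx(0.96)
        assert rep.dice == pytest.approx(0.80)
        assert rep.sensitivity == pytest.approx(0.80)
        assert rep.specificity == pytest.approx(88 / 90)
        assert rep.precision == pytest.approx(0.80)

    def test_perfect_prediction_all_ones(self):
        rep = E.metrics(E.ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (rep.accuracy, rep.dice, rep.sensitivity, rep.specificity,
                rep.precision) == (1, 1, 1, 1, 1)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            pred = rng.random((8, 8)) > 0.5
            gt_ab = rng.random((8, 8)) > 0.5
            gt = np.where(gt_ab, E.LABEL_ABNORMAL, E.LABEL_NORMAL).astype(
                np.int8)
            rep = E.metrics(E.confusion(pred, gt))
            ref = brute_force_metrics(pred, gt_ab)
            assert rep.accuracy == pytest.approx(ref["ac"], abs=1e-12)
            assert rep.dice == pytest.approx(ref["dc"], abs=1e-12)
            assert rep.sensitivity == pytest.approx(ref["se"], abs=1e-12)
            assert rep.specificity == pytest.approx(ref["sp"], abs=1e-12)
            assert rep.precision == pytest.approx(ref["pe"], abs=1e-12)

    def test_dice_harmonic_identity(self, rng):
        for _ in range(20):
            counts = E.ConfusionCounts(*(int(x) for x in
                                         rng.integers(1, 50, 4)))
            rep = E.metrics(counts)
            assert rep.dice == pytest.approx(
                2 * rep.precision * rep.sensitivity
                / (rep.precision + rep.sensitivity), abs=1e-12)

    def test_division_by_zero_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning):
            rep = E.metrics(E.ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert rep.sensitivity == 0.0


class TestAUC:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.8], [0.1, 0.2]])
        gt = np.array([[1, 1], [0, 0]], dtype=np.int8)
        assert E.auc(scores, gt) == 1.0

    def test_constant_scores_chance_level(self):
        scores = np.full((2, 3), 0.5)
        gt = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        assert E.auc(scores, gt) == pytest.approx(0.5)

    def test_six_pixel_toy_example(self):
        scores = np.array([[0.9, 0.8, 0.7], [0.4, 0.3, 0.2]])
        labels = np.array([[1, 1, 0], [1, 0, 0]], dtype=np.int8)
        expected = mann_whitney_auc(scores.ravel(),
                                    labels.ravel().astype(bool))
        assert E.auc(scores, labels) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(8 / 9)

    def test_matches_rank_oracle_on_random_instances(self, rng):
        for _ in range(100):
            scores = np.round(rng.random((6, 6)), 2)   # force ties
            labels = (rng.random((6, 6)) > 0.5)
            if labels.all() or not labels.any():
                continue
            gt = np.where(labels, E.LABEL_ABNORMAL, E.LABEL_NORMAL).astype(
                np.int8)
            ref = mann_whitney_auc(scores.ravel(), labels.ravel())
            assert E.auc(scores, gt) == pytest.approx(ref, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random((20, 20))
        labels = rng.random((20, 20)) > 0.6
        gt = np.where(labels, E.LABEL_ABNORMAL, E.LABEL_NORMAL).astype(np.int8)
        assert E.auc(scores, gt) == pytest.approx(
            roc_auc_score(labels.ravel(), scores.ravel()), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random((10, 10))
        labels = rng.random((10, 10)) > 0.5
        gt = np.where(labels, E.LABEL_ABNORMAL, E.LABEL_NORMAL).astype(np.int8)
        a = E.auc(scores, gt)
        b = E.auc(np.exp(3 * scores), gt)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            E.auc(np.random.rand(4, 4),
                  np.zeros((4, 4), dtype=np.int8))


class TestContourGroundTruth:
    def test_two_level_step_roi(self, rng):
        # two dominant levels with a narrow transition band at the step
        col = np.concatenate([np.full(17, 0.2),
                              np.linspace(0.2, 0.8, 6),
                              np.full(17, 0.8)])
        img = np.tile(col, (40, 1)) + rng.normal(0, 0.01, (40, 40))
        gt = E.contour_ground_truth(img, (0, 40, 0, 40), n_repeats=1)
        assert (gt.labels[:, :15] == E.LABEL_ABNORMAL).mean() > 0.95
        assert (gt.labels[:, 25:] == E.LABEL_NORMAL).mean() > 0.95
        buffer_cols = np.nonzero(
            (gt.labels == E.LABEL_BUFFER).mean(axis=0) > 0.5)[0]
        assert buffer_cols.size and buffer_cols.min() >= 15 \
            and buffer_cols.max() < 25

    def test_single_repeat_is_deterministic_and_brackets_otsu(self, rng):
        from scipy.ndimage import median_filter
        from skimage.filters import threshold_otsu

        img = rng.random((30, 30))
        a = E.contour_ground_truth(img, (0, 30, 0, 30), n_repeats=1)
        b = E.contour_ground_truth(img, (0, 30, 0, 30), n_repeats=1, seed=99)
        assert a.thresholds == b.thresholds   # no resampling for one repeat
        split = threshold_otsu(median_filter(img, 3, mode="nearest").ravel())
        assert a.thresholds[0] < split < a.thresholds[1]

    def test_default_three_repeats(self, rng):
        img = rng.random((30, 30))
        gt = E.contour_ground_truth(img, (0, 30, 0, 30))
        assert gt.n_repeats == 3

    def test_constant_roi_rejected(self):
        with pytest.raises(ValidationError):
            E.contour_ground_truth(np.ones((20, 20)), (0, 20, 0, 20))

    @pytest.mark.parametrize("severity,seed", [(0.6, 11), (0.6, 12),
                                               (0.8, 11), (0.8, 12)])
    def test_phantom_abnormal_region_overlaps_lesion(self, severity, seed):
        """The confidently-abnormal contour region recovers the lesion core
        (buffer band excluded, matching the confusion-count semantics)."""
        from ischemap import lsci, phantom

        cfg = phantom.PhantomConfig(
            size=(64, 64), n_frames=32,
            lesion=phantom.LesionSpec(radius=12, severity=severity,
                                      transition_width=4.0), seed=seed)
        sc = phantom.generate_scene(cfg)
        perf = np.log(lsci.contrast_to_flow(sc.lsci))  # log-perfusion scale
        ys, xs = np.nonzero(sc.lesion_mask | sc.transition_mask)
        pad = 4                              # ROI stays inside the tissue
        roi = (max(0, ys.min() - pad), min(64, ys.max() + pad),
               max(0, xs.min() - pad), min(64, xs.max() + pad))
        gt = E.contour_ground_truth(perf, roi, n_repeats=3)
        keep = gt.labels != E.LABEL_BUFFER
        pred = (gt.labels == E.LABEL_ABNORMAL) & keep
        truth = sc.lesion_mask[roi[0]:roi[1], roi[2]:roi[3]] & keep
        dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
        assert dice >= 0.8
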