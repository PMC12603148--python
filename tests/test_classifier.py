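"""Multi-view classifier: architecture, augmentation, batching, recipe."""

from __future__ import annotations

import numpy as np
import pytest

from lucent.classifier import (
    AugmentConfig2D,
    ClassifierConfig,
    augment_view,
    balanced_batches,
    build_classifier,
    focal_loss_logits,
    predict_patient,
    softmax,
    train_classifier,
    view_dropout,
)
from lucent.segnet import FocalParams


def _toy_items(n_pos, n_neg, rng, n_views=4, size=16, signal=0.5):
    """Trivially separable synthetic view sets."""
    items = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        base = rng.random((n_views, size, size)).astype(np.float32) * 0.3
        if pos:
            base[:, :4, :4] += signal
        items.append((f"P{i:03d}", np.clip(base, 0, 1), "FBA" if pos else "NFBA"))
    return items


class TestArchitecture:
    def test_softmax_probabilities_sum_to_one(self):
        m = build_classifier(ClassifierConfig(input_size=16))
        x = np.random.default_rng(0).random((5, 1, 16, 16)).astype(np.float32)
        p = softmax(m.forward(x, train=False))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic_despite_dropout(self):
        m = build_classifier(ClassifierConfig(input_size=16, dropout_p=0.5))
        x = np.random.default_rng(1).random((3, 1, 16, 16)).astype(np.float32)
        assert np.array_equal(m.forward(x, train=False), m.forward(x, train=False))

    def test_tiny_much_smaller_than_resnet18(self):
        tiny = build_classifier(ClassifierConfig(input_size=64))
        full = build_classifier(ClassifierConfig(backbone="resnet18",
                                                 in_channels=3))
        assert tiny.n_params() < full.n_params() / 20

    def test_pretrained_flag_raises_offline(self):
        with pytest.raises(RuntimeError, match="offline"):
            build_classifier(ClassifierConfig(pretrained=True))

    def test_focal_logit_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((6, 2))
        y = np.array([0, 1, 1, 0, 1, 0])
        _, g = focal_loss_logits(logits, y, FocalParams())
        eps = 1e-6
        for i in [(0, 0), (3, 1), (5, 0)]:
            lp, lm = logits.copy(), logits.copy()
            lp[i] += eps
            lm[i] -= eps
            num = (focal_loss_logits(lp, y, FocalParams())[0]
                   - focal_loss_logits(lm, y, FocalParams())[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4)


class TestAugmentation:
    def test_disabled_config_is_identity(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32)).astype(np.float32)
        out = augment_view(img, AugmentConfig2D.disabled(), rng)
        assert np.array_equal(out, img)

    def test_occlusion_area_bounded_by_circle(self):
        rng = np.random.default_rng(4)
        img = np.ones((64, 64), np.float32)
        cfg = AugmentConfig2D(affine_frac=0.0, jitter_frac=0.0,
                              occlusion_prob=1.0, occlusion_radius=(0.25, 0.25))
        removed = [(augment_view(img, cfg, rng) == 0).mean() for _ in range(50)]
        assert max(removed) <= np.pi * 0.25 ** 2 + 0.01

    def test_seeded_rng_reproducible(self):
        img = np.random.default_rng(5).random((32, 32)).astype(np.float32)
        cfg = AugmentConfig2D()
        a = augment_view(img, cfg, np.random.default_rng(77))
        b = augment_view(img, cfg, np.random.default_rng(77))
        assert np.array_equal(a, b)

    def test_output_stays_in_unit_interval(self):
        rng = np.random.default_rng(6)
        img = rng.random((32, 32)).astype(np.float32)
        for _ in range(20):
            out = augment_view(img, AugmentConfig2D(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestViewDropout:
    def test_removes_one_or_two_of_twelve(self):
        rng = np.random.default_rng(7)
        views = np.zeros((12, 8, 8), np.float32)
        cfg = AugmentConfig2D(view_dropout_prob=1.0)
        seen = {len(view_dropout(views, cfg, rng)) for _ in range(200)}
        assert seen == {10, 11}

    def test_disabled_is_identity(self):
        views = np.zeros((12, 8, 8), np.float32)
        out = view_dropout(views, AugmentConfig2D(view_dropout_prob=0.0),
                           np.random.default_rng(0))
        assert out.shape == (12, 8, 8)

    def test_too_few_views_rejected(self):
        with pytest.raises(ValueError):
            view_dropout(np.zeros((2, 8, 8)), AugmentConfig2D(),
                         np.random.default_rng(0))


class TestBalancedBatches:
    def test_every_batch_8_plus_8(self):
        rng = np.random.default_rng(8)
        ids = [f"P{i}" for i in range(70)]
        labels = np.array([1] * 14 + [0] * 56)
        batches = balanced_batches(ids, labels, 16, rng)
        assert len(batches) == 7  # 56 majority / 8 per batch
        for b in batches:
            pos = sum(1 for p in b if int(p[1:]) < 14)
            assert pos == 8 and len(b) == 16

    def test_seeds_change_order_not_composition(self):
        ids = [f"P{i}" for i in range(20)]
        labels = np.array([1] * 10 + [0] * 10)
        b1 = balanced_batches(ids, labels, 4, np.random.default_rng(1))
        b2 = balanced_batches(ids, labels, 4, np.random.default_rng(2))
        assert b1 != b2
        for b in b1 + b2:
            assert sum(1 for p in b if int(p[1:]) < 10) == 2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_batches(["a", "b"], np.array([1, 1]), 2,
                             np.random.default_rng(0))


class TestPrediction:
    def test_mean_of_constant_views(self):
        m = build_classifier(ClassifierConfig(input_size=16))
        views = np.tile(np.random.default_rng(9).random((1, 16, 16)), (12, 1, 1))
        pp = predict_patient(m, views.astype(np.float32),
                             ClassifierConfig(input_size=16), "P0")
        assert np.allclose(pp.aggregate_prob, pp.per_view_probs.mean(axis=0))
        assert pp.aggregate_prob.sum() == pytest.approx(1.0, abs=1e-6)

    def test_aggregation_permutation_invariant(self):
        rng = np.random.default_rng(10)
        m = build_classifier(ClassifierConfig(input_size=16))
        views = rng.random((6, 16, 16)).astype(np.float32)
        cfg = ClassifierConfig(input_size=16)
        a = predict_patient(m, views, cfg, "P0").aggregate_prob
        b = predict_patient(m, views[::-1].copy(), cfg, "P0").aggregate_prob
        assert np.allclose(a, b, atol=1e-6)

    def test_exact_half_ties_to_nfba(self):
        # documented tie rule: strict > at threshold 0.5
        class Stub:
            def forward(self, x, train=False):
                return np.zeros((len(x), 2))  # SoftMax -> (0.5, 0.5)

        pp = predict_patient(Stub(), np.zeros((4, 8, 8), np.float32),
                             ClassifierConfig(), "P0")
        assert pp.aggregate_prob[1] == pytest.approx(0.5)
        assert pp.label_pred == "NFBA"

    def test_threshold_monotone(self):
        class Stub:
            def forward(self, x, train=False):
                return np.tile([0.0, 1.0], (len(x), 1))

        views = np.zeros((4, 8, 8), np.float32)
        calls = [predict_patient(Stub(), views,
                                 ClassifierConfig(threshold=t), "P0").label_pred
                 for t in (0.3, 0.5, 0.9)]
        # raising the threshold never converts NFBA into FBA
        assert "".join(c[0] for c in calls) in ("FFF", "FFN", "FNN", "NNN")

    def test_empty_viewset_raises(self):
        m = build_classifier(ClassifierConfig(input_size=16))
        with pytest.raises(ValueError):
            predict_patient(m, np.zeros((0, 16, 16)), ClassifierConfig(), "P0")


class TestTrainingRecipe:
    def _run(self, max_epochs=30, lr0=1e-3, bn_momentum=0.2):
        rng = np.random.default_rng(11)
        items = _toy_items(8, 8, rng)
        pos, neg = items[:8], items[8:]
        cfg = ClassifierConfig(input_size=16, lr0=lr0, max_epochs=max_epochs,
                               batch_size=4, seed=1, bn_momentum=bn_momentum)
        return train_classifier(pos[:5] + neg[:5], pos[5:] + neg[5:], cfg,
                                AugmentConfig2D.disabled())

    def test_leakage_guard(self):
        rng = np.random.default_rng(12)
        items = _toy_items(4, 4, rng)
        with pytest.raises(ValueError, match="leakage"):
            train_classifier(items, items[:2], ClassifierConfig(input_size=16))

    def test_plateau_drops_lr_after_exactly_five_epochs(self):
        # a frozen-loss stub exercises the schedule bookkeeping exactly
        model, hist = self._run(max_epochs=12, lr0=1e-3)
        lrs = hist["lr"]
        # whenever 5 consecutive non-improving epochs occur, lr drops x0.1
        best = np.inf
        plateau = 0
        expect = [1e-3]
        lr = 1e-3
        for vl in hist["val_loss"][:-1]:
            if vl < best * (1 - 1e-4):
                best, plateau = vl, 0
            else:
                plateau += 1
                if plateau == 5:
                    lr *= 0.1
                    plateau = 0
            expect.append(lr)
        assert np.allclose(lrs, expect[:len(lrs)])

    def test_early_stop_after_ten_stalled_epochs(self):
        # vanishing lr and frozen BN stats: validation loss cannot improve
        model, hist = self._run(max_epochs=50, lr0=1e-12, bn_momentum=0.0)
        assert len(hist["val_loss"]) <= 11  # 1 baseline + 10 stalled

    def test_learns_separable_toy_problem(self):
        model, hist = self._run(max_epochs=20)
        assert max(hist["val_f1"]) >= 0.8


class TestEndToEndRecovery:
    def test_heldout_patient_accuracy_and_auc(self, clf_training_run):
        from lucent.evalstats import roc_auc

        model, cfg, test, _ = clf_training_run
        truth, pred, score = [], [], []
        for pid, views, lab in test:
            pp = predict_patient(model, views, cfg, pid, lab)
            truth.append(lab == "FBA")
            pred.append(pp.label_pred == "FBA")
            score.append(pp.aggregate_prob[1])
        truth = np.array(truth)
        acc = float((np.array(pred) == truth).mean())
        assert acc >= 0.85
        assert roc_auc(score, truth) >= 0.90
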