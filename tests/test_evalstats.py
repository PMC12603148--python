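"""Classification metrics and paired-statistics tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lucent.evalstats import (
    ClassMetrics,
    ConfusionCounts,
    bootstrap_f1_ci,
    class_metrics,
    confusion,
    delong_test,
    discordant_counts,
    mcnemar,
    roc_auc,
    roc_curve_points,
    stratified_kfold,
)


class TestConfusion:
    def test_perfect_prediction(self):
        t = [1] * 5 + [0] * 3
        cc = confusion(t, t)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (5, 0, 3, 0)

    def test_all_negative_prediction(self):
        cc = confusion([1, 1, 0], [0, 0, 0])
        assert cc.tp == 0 and cc.fp == 0 and cc.fn == 2

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.random(20) > 0.5
        p = rng.random(20) > 0.5
        cc = confusion(t, p)
        tally = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
        for a, b in zip(t, p):
            tally[("tp" if b else "fn") if a else ("fp" if b else "tn")] += 1
        assert cc.__dict__ == tally

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestClassMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # printed confusion tables reproduce exactly at 1-decimal rounding
        ((32, 9, 221, 6), (94.4, 84.2, 78.0, 81.0)),
        ((16, 5, 77, 5), (90.3, 76.2, 76.2, 76.2)),
        ((10, 4, 53, 3), (90.0, 76.9, 71.4, 74.1)),
        ((5, 9, 56, 0), (87.1, 100.0, 35.7, 52.6)),
    ])
    def test_published_confusion_tables(self, counts, expected):
        m = class_metrics(ConfusionCounts(*counts)).rounded()
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == expected

    def test_undefined_marked_not_zero(self):
        m = class_metrics(ConfusionCounts(0, 0, 5, 0))
        assert m.precision is None and m.recall is None and m.f1 is None

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_identities_on_random_counts(self, counts):
        tp, fn, tn, fp = counts
        cc = ConfusionCounts(tp, fn, tn, fp)
        m = class_metrics(cc)
        if cc.total:
            assert m.accuracy == pytest.approx(100 * (tp + tn) / cc.total, abs=1e-12)
        if m.f1 is not None:
            assert m.f1 == pytest.approx(100 * 2 * tp / (2 * tp + fp + fn), abs=1e-9)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        scores = [0.9, 0.4, 0.6, 0.3, 0.6, 0.1]
        truth = [1, 1, 1, 0, 0, 0]
        wins = ties = 0
        for sp in [0.9, 0.4, 0.6]:
            for sn in [0.3, 0.6, 0.1]:
                wins += sp > sn
                ties += sp == sn
        assert roc_auc(scores, truth) == pytest.approx((wins + 0.5 * ties) / 9)

    def test_one_class_absent_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints(self):
        fpr, tpr, _ = roc_curve_points([0.9, 0.1], [1, 0])
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(1)
        t = rng.random(30) > 0.5
        s = rng.random(30)
        a1, a2, p = delong_test(s, s, t)
        assert a1 == a2 and p == 1.0

    def test_aucs_agree_with_rank_auc(self):
        rng = np.random.default_rng(2)
        t = rng.random(40) > 0.4
        sa, sb = rng.random(40), rng.random(40)
        a1, a2, _ = delong_test(sa, sb, t)
        assert a1 == pytest.approx(roc_auc(sa, t), abs=1e-12)
        assert a2 == pytest.approx(roc_auc(sb, t), abs=1e-12)

    def test_p_close_to_permutation_oracle(self):
        # paired sign-flip permutation of the AUC difference, 10k reps
        rng = np.random.default_rng(3)
        n = 30
        t = np.array([True] * 12 + [False] * 18)
        base = rng.random(n)
        sa = base + 0.45 * t + 0.12 * rng.random(n)
        sb = base + 0.25 * t + 0.12 * rng.random(n)
        _, _, p = delong_test(sa, sb, t)
        diff_obs = abs(roc_auc(sa, t) - roc_auc(sb, t))
        count = 0
        reps = 10000
        for _ in range(reps):
            swap = rng.random(n) < 0.5
            xa = np.where(swap, sb, sa)
            xb = np.where(swap, sa, sb)
            if abs(roc_auc(xa, t) - roc_auc(xb, t)) >= diff_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / reps, abs=0.02)


class TestMcNemar:
    def test_symmetric_counts_p_one(self):
        assert mcnemar(4, 4) == 1.0

    def test_exact_binomial_tail(self):
        assert mcnemar(9, 0) == pytest.approx(2 * 0.5 ** 9)

    def test_continuity_corrected_chisquare(self):
        from scipy import stats

        # (|20-5|-1)^2 / 25 = 7.84
        assert mcnemar(20, 5) == pytest.approx(stats.chi2.sf(7.84, 1), rel=1e-12)
        assert mcnemar(20, 5) == pytest.approx(0.0051, abs=2e-4)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            b, c = rng.integers(0, 40, 2)
            if b + c == 0:
                continue
            p = mcnemar(b, c)
            assert 0.0 < p <= 1.0
            assert p == mcnemar(c, b)

    def test_no_discordant_pairs_undefined(self):
        assert np.isnan(mcnemar(0, 0))

    def test_discordant_counts_helper(self):
        t = [1, 1, 0, 0, 1]
        a = [1, 0, 0, 1, 1]
        b = [0, 0, 0, 0, 1]
        # case 0: A right B wrong; case 3: B right A wrong
        assert discordant_counts(t, a, b) == (1, 1)


class TestBootstrap:
    def test_perfect_prediction_degenerate_interval(self):
        t = [1] * 4 + [0] * 6
        f1, lo, hi = bootstrap_f1_ci(t, t, n_boot=200, seed=0)
        assert f1 == 100.0 and lo == 100.0 and hi == 100.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        t = rng.random(60) > 0.7
        p = t ^ (rng.random(60) < 0.2)
        for seed in range(5):
            f1, lo, hi = bootstrap_f1_ci(t, p, n_boot=300, seed=seed)
            assert lo <= f1 <= hi

    def test_interval_narrows_with_cohort_size(self):
        rng = np.random.default_rng(6)
        widths = {n: [] for n in (40, 160)}
        for n in widths:
            for seed in range(20):
                t = np.tile([1, 0, 0, 0], n // 4).astype(bool)
                p = t ^ (rng.random(n) < 0.15)
                if not t[p].any():
                    continue
                _, lo, hi = bootstrap_f1_ci(t, p, n_boot=200, seed=seed)
                widths[n].append(hi - lo)
        assert np.mean(widths[160]) < np.mean(widths[40])

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            bootstrap_f1_ci([0, 0, 0], [0, 1, 0])


class TestStratifiedKFold:
    def test_cohort_14_56_fold_composition(self):
        ids = [f"P{i}" for i in range(70)]
        labels = ["FBA"] * 14 + ["NFBA"] * 56
        folds = stratified_kfold(ids, labels, k=5, seed=1)
        for f in range(5):
            members = [i for i in ids if folds[i] == f]
            pos = sum(1 for m in members if int(m[1:]) < 14)
            assert pos in (2, 3)
            assert len(members) - pos in (11, 12)

    def test_partition_property(self):
        ids = [f"P{i}" for i in range(30)]
        labels = [i % 2 for i in range(30)]
        folds = stratified_kfold(ids, labels, k=5, seed=2)
        assert set(folds) == set(ids)           # every patient assigned once
        assert set(folds.values()) == set(range(5))

    def test_deterministic_in_seed(self):
        ids = [f"P{i}" for i in range(20)]
        labels = [i % 2 for i in range(20)]
        assert stratified_kfold(ids, labels, 5, seed=3) == \
               stratified_kfold(ids, labels, 5, seed=3)

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            stratified_kfold(list("abcdef"), [1, 0, 0, 0, 0, 0], k=5)
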