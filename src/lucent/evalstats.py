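"""Patient-level classification evaluation and paired statistics.

Covers the confusion-count arithmetic (accuracy, precision, recall, F1),
rank-based ROC AUC, DeLong's test for correlated AUCs, McNemar's paired
test (exact binomial for small discordant counts, continuity-corrected
chi-square otherwise), percentile-bootstrap F1 confidence intervals, and
stratified patient-level k-fold assignment.

Metric percentages are displayed rounded to one decimal; full precision is
retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ClassMetrics:
    """Accuracy/precision/recall/F1 in percent; None marks an undefined value."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None

    def rounded(self) -> dict:
        """Display form: one-decimal percentages, None where undefined."""
        return {k: (None if v is None else round(v, 1))
                for k, v in self.__dict__.items()}


def confusion(truth, pred) -> ConfusionCounts:
    """Tally binary outcome vectors into TP/FN/TN/FP counts."""
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    tp = int((truth & pred).sum())
    fn = int((truth & ~pred).sum())
    tn = int((~truth & ~pred).sum())
    fp = int((~truth & pred).sum())
    return ConfusionCounts(tp, fn, tn, fp)


def class_metrics(cc: ConfusionCounts) -> ClassMetrics:
    """Accuracy, precision, recall and F1 (harmonic mean) in percent.

    Undefined ratios (zero denominators) are returned as None, never as a
    silent zero.
    """
    tp, fn, tn, fp = cc.tp, cc.fn, cc.tn, cc.fp
    acc = 100.0 * (tp + tn) / cc.total if cc.total > 0 else None
    prec = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    rec = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    if prec is None or rec is None or (prec + rec) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return ClassMetrics(acc, prec, rec, f1)


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------


def roc_auc(scores, truth) -> float:
    """Rank-based AUC: P(random positive outscores a random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    npos = int(truth.sum())
    nneg = int((~truth).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[truth].sum() - npos * (npos + 1) / 2.0) / (npos * nneg))


def roc_curve_points(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) sweeping the decision threshold over the scores."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    thr = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thr:
        pred = scores >= t
        tpr.append(float((pred & truth).sum() / truth.sum()))
        fpr.append(float((pred & ~truth).sum() / (~truth).sum()))
    return np.array(fpr), np.array(tpr), np.concatenate([[np.inf], thr])


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def delong_test(scores_a, scores_b, truth) -> tuple[float, float, float]:
    """DeLong comparison of two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, two-sided p) using the midrank structural
    components and the asymptotic normal distribution of the paired AUC
    difference. Identical classifiers (zero difference, zero variance)
    return p = 1; otherwise a zero variance raises.
    """
    truth = np.asarray(truth).astype(bool)
    scores = np.stack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    if scores.shape[1] != truth.size:
        raise ValueError("scores and truth must be paired (same patients)")
    m = int(truth.sum())
    n = int((~truth).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    pos = scores[:, truth]
    neg = scores[:, ~truth]
    k = 2
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10 / m + s01 / n)
    l = np.array([1.0, -1.0])
    var_diff = float(l @ var @ l)
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0 or not np.isfinite(var_diff):
        if abs(diff) < 1e-12:
            return float(aucs[0]), float(aucs[1]), 1.0
        raise ValueError("degenerate scores: zero variance of the AUC difference")
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), min(p, 1.0)


# --------------------------------------------------------------------------
# paired tests / resampling
# --------------------------------------------------------------------------


def mcnemar(b_discordant: int, c_discordant: int, exact_threshold: int = 25) -> float:
    """McNemar's test on discordant-pair counts.

    Exact two-sided binomial when b + c < ``exact_threshold``; otherwise the
    continuity-corrected chi-square (|b-c|-1)^2/(b+c) on 1 df. Returns the
    two-sided p-value; b + c = 0 is undefined and returns NaN.
    """
    b, c = int(b_discordant), int(c_discordant)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    nd = b + c
    if nd == 0:
        return float("nan")
    if nd < exact_threshold:
        res = stats.binomtest(min(b, c), nd, 0.5, alternative="two-sided")
        return float(res.pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / nd
    return float(stats.chi2.sf(chi2, df=1))


def discordant_counts(truth, pred_a, pred_b) -> tuple[int, int]:
    """(b, c): cases A gets right and B wrong, and vice versa."""
    truth = np.asarray(truth).astype(bool)
    pa = np.asarray(pred_a).astype(bool)
    pb = np.asarray(pred_b).astype(bool)
    ok_a = pa == truth
    ok_b = pb == truth
    return int((ok_a & ~ok_b).sum()), int((~ok_a & ok_b).sum())


def _f1_frac(truth: np.ndarray, pred: np.ndarray) -> float | None:
    tp = int((truth & pred).sum())
    fp = int((~truth & pred).sum())
    fn = int((truth & ~pred).sum())
    denom = 2 * tp + fp + fn
    return None if denom == 0 else 2.0 * tp / denom


def bootstrap_f1_ci(truth, pred, n_boot: int = 1000, seed: int = 0,
                    max_redraws: int = 100000) -> tuple[float, float, float]:
    """Patient-level percentile bootstrap 95% CI for the F1 score (percent).

    Resamples with undefined F1 (no true or predicted positives) are redrawn;
    the redraw count is reported via a warning if nonzero.
    """
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.sum() == 0:
        raise ValueError("bootstrap_f1_ci requires at least one positive case")
    point = _f1_frac(truth, pred)
    rng = np.random.default_rng(seed)
    n = truth.size
    vals = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            f1 = _f1_frac(truth[idx], pred[idx])
            if f1 is not None:
                vals[i] = f1
                break
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
    if redraws:
        import warnings
        warnings.warn(f"redrew {redraws} degenerate bootstrap resamples", stacklevel=2)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return 100.0 * point, 100.0 * float(lo), 100.0 * float(hi)


def stratified_kfold(patient_ids, labels, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Stratified patient-level fold assignment: patient_id -> fold index.

    Every patient lands in exactly one fold and per-fold class counts are
    within one patient of the stratified ideal. Deterministic in ``seed``.
    """
    patient_ids = list(patient_ids)
    labels = np.asarray(labels)
    if len(patient_ids) != len(labels):
        raise ValueError("patient_ids and labels must align")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} patients < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            assignment[patient_ids[i]] = fold
    return assignment
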