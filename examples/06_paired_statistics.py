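"""Evaluation statistics on a worked example.

Starting from patient-level confusion counts of two readers of the same
70-patient cohort (a deep model: TP 10, FN 4, TN 53, FP 3; expert readers:
TP 5, FN 9, TN 56, FP 0), computes the classification metrics, McNemar's
paired test on the discordant calls, a 1000-rep bootstrap 95% CI for F1,
and DeLong's test on simulated paired scores.
"""

import numpy as np

from lucent.evalstats import (ConfusionCounts, bootstrap_f1_ci, class_metrics,
                              confusion, delong_test, discordant_counts,
                              mcnemar, roc_auc)

def vectors(tp, fn, tn, fp):
    truth = np.array([True] * (tp + fn) + [False] * (tn + fp))
    pred = np.array([True] * tp + [False] * fn + [False] * tn + [True] * fp)
    return truth, pred

truth, model_pred = vectors(10, 4, 53, 3)
_, reader_pred = vectors(5, 9, 56, 0)

for name, pred in [("model", model_pred), ("readers", reader_pred)]:
    m = class_metrics(confusion(truth, pred)).rounded()
    print(f"{name:>8}: accuracy {m['accuracy']}%  precision {m['precision']}%  "
          f"recall {m['recall']}%  F1 {m['f1']}%")

b, c = discordant_counts(truth, model_pred, reader_pred)
print(f"\ndiscordant pairs: model-only-right b={b}, readers-only-right c={c}")
print(f"McNemar two-sided p = {mcnemar(b, c):.4f} "
      "(exact binomial, b+c < 25)")

f1, lo, hi = bootstrap_f1_ci(truth, model_pred, n_boot=1000, seed=0)
print(f"model F1 {f1:.1f}% with bootstrap 95% CI [{lo:.1f}, {hi:.1f}]%")

rng = np.random.default_rng(1)
s_model = np.clip(0.35 + 0.35 * truth + 0.15 * rng.standard_normal(70), 0, 1)
s_reader = np.clip(0.40 + 0.20 * truth + 0.15 * rng.standard_normal(70), 0, 1)
a1, a2, p = delong_test(s_model, s_reader, truth)
print(f"\nDeLong on simulated paired scores: AUC {a1:.3f} vs {a2:.3f}, p = {p:.3f}")
print("a small p would mean the two score vectors rank patients differently")
print("beyond what their shared cohort explains.")
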