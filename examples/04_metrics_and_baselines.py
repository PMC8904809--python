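"""Evaluation toolbox: per-drug analyses, frequency baselines, fold tests.

Builds a small set of labelled predictions by hand and walks through
the analysis procedures: confusion metrics, ROC/PR AUC, per-drug AUC
with single-target exclusion, the per-drug probability "distance", the
THR_k% protein-frequency baselines, and the paired fold-wise t-test
used to compare methods.
"""

from hidti.core_data import PairSet
from hidti.evaluation import (
    PredictionRecord,
    compare_folds_ttest,
    confusion_counts,
    drug_distance,
    per_drug_auc,
    pr_auc,
    precision_recall_f1,
    roc_auc,
    thr_baseline,
)

records = [
    PredictionRecord("dA", "p1", 0.92, 1),
    PredictionRecord("dA", "p2", 0.81, 1),
    PredictionRecord("dA", "p3", 0.35, 0),
    PredictionRecord("dA", "p4", 0.15, 0),
    PredictionRecord("dB", "p1", 0.70, 1),
    PredictionRecord("dB", "p5", 0.60, 0),
    PredictionRecord("dC", "p2", 0.40, 1),  # dC has a single (positive) pair
]

tp, fp, tn, fn = confusion_counts(records)
precision, recall, f1 = precision_recall_f1((tp, fp, tn, fn))
print(f"confusion at 0.5: TP={tp} FP={fp} TN={tn} FN={fn}")
print(f"precision {precision:.3f}, recall {recall:.3f}, F1 {f1:.3f}")
print(f"ROC AUC {roc_auc(records):.3f}, PR AUC {pr_auc(records):.3f}")

table, excluded = per_drug_auc(records)
print("\nper-drug AUC (single-class drugs excluded):")
print(table.to_string(index=False))
print(f"excluded: {list(excluded.drug)}")

print("\nper-drug distance |mean p(pos) - mean p(neg)|:")
print(drug_distance(records).to_string(index=False))

# a protein seen mostly positive in training drives the THR rule
train = PairSet(
    [(f"d{i}", "pHub", 1 if i < 7 else 0) for i in range(10)]
    + [(f"d{i}", "pRare", 1 if i == 0 else 0) for i in range(10)],
    role="train",
)
test = PairSet([("dZ", "pHub", 1), ("dZ", "pRare", 0)], role="test")
for thr in (0.25, 0.50, 0.75):
    recs, metrics = thr_baseline(train, test, thr)
    preds = {r.protein_id: int(r.probability) for r in recs}
    print(f"THR_{int(thr * 100)}%: predictions {preds}, F1 {metrics['f1']:.2f}")

auc_a = [0.84, 0.86, 0.83, 0.88, 0.85, 0.87, 0.82, 0.86, 0.85, 0.84]
auc_b = [0.80, 0.83, 0.80, 0.84, 0.82, 0.83, 0.79, 0.82, 0.82, 0.81]
print(f"\npaired t-test over 10 fold AUCs: p = {compare_folds_ttest(auc_a, auc_b):.2e}")
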