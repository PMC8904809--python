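"""Metrics and analysis procedures for DTI predictions.

Covers confusion-matrix metrics (precision/recall/F1), ROC and
precision-recall AUC, per-drug breakdowns (AUC by number of targets and
the positive/negative mean-probability distance), protein-frequency
threshold baselines (THR_k%), and paired fold-wise significance tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PairSet


@dataclass
class PredictionRecord:
    drug_id: str
    protein_id: str
    probability: float
    label: int
    fold: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.probability):
            raise ValueError("probability must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be 0/1")


def _probs_labels(records) -> tuple[np.ndarray, np.ndarray]:
    probs = np.array([r.probability for r in records], dtype=float)
    labels = np.array([r.label for r in records], dtype=int)
    return probs, labels


def confusion_counts(records, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with 'predicted positive iff probability >= threshold'."""
    if len(records) == 0:
        raise ValueError("no records")
    probs, labels = _probs_labels(records)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def precision_recall_f1(counts: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean.

    Degenerate 0/0 ratios are defined as 0.
    """
    tp, fp, tn, fn = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


class SingleClassError(ValueError):
    """Raised when an AUC is requested for records of a single class."""


def roc_auc(records) -> float:
    """ROC AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    probs, labels = _probs_labels(records)
    return roc_auc_scores(probs, labels)


def roc_auc_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: needs both classes")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def pr_auc(records) -> float:
    """Area under the precision-recall curve by step integration over recall.

    Equivalent to average precision: each distinct score threshold
    contributes (recall increment) x (precision at that threshold).
    """
    probs, labels = _probs_labels(records)
    return pr_auc_scores(probs, labels)


def pr_auc_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == labels.size:
        raise SingleClassError("PR AUC undefined: needs both classes")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores so precision is evaluated per distinct threshold
    tp = np.cumsum(y)
    n = np.arange(1, y.size + 1)
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tp_g, n_g = tp[last_of_group], n[last_of_group]
    recall = tp_g / n_pos
    precision = tp_g / n_g
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class EvalReport:
    """Per-fold metrics and their mean/sd aggregates."""

    per_fold: pd.DataFrame
    tag: str = ""
    extras: dict = field(default_factory=dict)

    METRICS = ("auc", "aucpr", "precision", "recall", "f1")

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.per_fold[metric].std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    def summary(self) -> str:
        parts = [
            f"{m}={self.mean(m):.3f}±{self.sd(m):.3f}" for m in self.METRICS
        ]
        head = f"[{self.tag}] " if self.tag else ""
        return head + " ".join(parts)


def evaluate_records(records, threshold: float = 0.5) -> dict[str, float]:
    """All scalar metrics for one set of prediction records."""
    counts = confusion_counts(records, threshold)
    precision, recall, f1 = precision_recall_f1(counts)
    return {
        "auc": roc_auc(records),
        "aucpr": pr_auc(records),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n": len(records),
    }


def report_from_folds(fold_records: dict[int, list], tag: str = "") -> EvalReport:
    """Per-fold metrics table; AUCs are computed per fold then averaged."""
    rows = []
    for fold, recs in sorted(fold_records.items()):
        row = {"fold": fold, **evaluate_records(recs)}
        rows.append(row)
    return EvalReport(pd.DataFrame(rows).set_index("fold"), tag=tag)


def per_drug_auc(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AUC per drug over that drug's test pairs.

    Drugs whose pairs are single-class (including single-target drugs)
    have no computable AUC; they are returned in a separate exclusion
    table so the record count is conserved.
    """
    by_drug: dict[str, list] = {}
    for r in records:
        by_drug.setdefault(r.drug_id, []).append(r)
    kept, excluded = [], []
    for drug, recs in sorted(by_drug.items()):
        n_targets = sum(r.label == 1 for r in recs)
        try:
            auc = roc_auc(recs)
        except SingleClassError:
            excluded.append({"drug": drug, "n_records": len(recs), "n_targets": n_targets})
            continue
        kept.append(
            {"drug": drug, "n_records": len(recs), "n_targets": n_targets, "auc": auc}
        )
    return pd.DataFrame(kept), pd.DataFrame(excluded)


def drug_distance(records, threshold: float = 0.5) -> pd.DataFrame:
    """Per drug: |mean prob of predicted-positive - mean prob of predicted-negative|.

    Drugs whose records fall in a single predicted class are excluded
    (distance undefined) and flagged in the returned table.
    """
    by_drug: dict[str, list] = {}
    for r in records:
        by_drug.setdefault(r.drug_id, []).append(r)
    rows = []
    for drug, recs in sorted(by_drug.items()):
        probs = np.array([r.probability for r in recs])
        pos = probs[probs >= threshold]
        neg = probs[probs < threshold]
        if pos.size == 0 or neg.size == 0:
            rows.append({"drug": drug, "distance": np.nan, "defined": False})
        else:
            rows.append(
                {
                    "drug": drug,
                    "distance": float(abs(pos.mean() - neg.mean())),
                    "defined": True,
                }
            )
    return pd.DataFrame(rows)


def thr_baseline(
    train: PairSet, test: PairSet, threshold: float
) -> tuple[list[PredictionRecord], dict[str, float]]:
    """Protein-frequency baseline THR_k%.

    For each protein, its positive ratio is (positive train pairs of the
    protein) / (all train pairs of the protein); proteins absent from
    training get ratio 0.  Every test pair of that protein is predicted
    positive (probability 1) iff the ratio >= threshold, else negative
    (probability 0).
    """
    pos_counts: dict[str, int] = {}
    tot_counts: dict[str, int] = {}
    for _, p, lab in train.pairs:
        tot_counts[p] = tot_counts.get(p, 0) + 1
        if lab == 1:
            pos_counts[p] = pos_counts.get(p, 0) + 1
    records = []
    for d, p, lab in test.pairs:
        ratio = pos_counts.get(p, 0) / tot_counts[p] if p in tot_counts else 0.0
        prob = 1.0 if ratio >= threshold else 0.0
        records.append(PredictionRecord(d, p, prob, lab))
    counts = confusion_counts(records)
    precision, recall, f1 = precision_recall_f1(counts)
    return records, {"precision": precision, "recall": recall, "f1": f1}


def compare_folds_ttest(auc_a, auc_b) -> float:
    """Two-sided paired t-test over per-fold AUCs of two methods.

    Conventions for degenerate inputs: identical vectors give p = 1;
    constant nonzero differences (zero variance, nonzero mean) give
    p = 0.0, below any machine-representable significance floor.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold AUC vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two folds")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)
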