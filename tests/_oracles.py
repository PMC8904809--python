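"""Independent brute-force implementations used as test oracles.

These deliberately share no code with the package: plain dense algebra,
exhaustive pair counting and closed forms, kept simple enough to be
checked by eye.
"""

from __future__ import annotations

import numpy as np


def layer_norm_oracle(x: np.ndarray, gain: np.ndarray, bias: np.ndarray, eps: float) -> np.ndarray:
    mu = x.mean()
    var = np.mean((x - mu) ** 2)  # biased
    return gain * (x - mu) / np.sqrt(var + eps) + bias


def residual_block_oracle(
    x: np.ndarray,
    W1: np.ndarray, b1: np.ndarray,
    W2: np.ndarray, b2: np.ndarray,
    W3: np.ndarray, b3: np.ndarray,
    g1: np.ndarray, c1: np.ndarray,
    g2: np.ndarray, c2: np.ndarray,
    eps: float,
) -> np.ndarray:
    """y = ReLU(LN(W2 ReLU(LN(W1 x)) + W3 x)) with weights as (out, in)."""
    h = W1 @ x + b1
    r = np.maximum(layer_norm_oracle(h, g1, c1, eps), 0.0)
    f = W2 @ r + b2
    s = f + W3 @ x + b3
    return np.maximum(layer_norm_oracle(s, g2, c2, eps), 0.0)


def sigmoid_oracle(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def bce_oracle(probs: np.ndarray, labels: np.ndarray, clamp: float = 1e-7) -> float:
    total = 0.0
    for p, t in zip(probs, labels):
        p = min(max(p, clamp), 1 - clamp)
        total += -t * np.log(p) - (1 - t) * np.log(1 - p)
    return total / len(probs)


def roc_auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive concordant-pair counting; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def precision_recall_f1_oracle(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def paired_t_pvalue_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook paired two-sided t-test via the t distribution."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return float(2 * tdist.sf(abs(t_stat), df=n - 1))
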