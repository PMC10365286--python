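"""Loss functions returning (scalar value, gradient w.r.t. the first input)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch; labels are integer class ids."""
    n = logits.shape[0]
    p = softmax(logits)
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(nll.mean()), (grad / n).astype(np.float32)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    weights: np.ndarray | None = None):
    """Weighted-mean binary cross-entropy on raw logits (stable form)."""
    logits = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if logits.size == 0:
        return 0.0, np.zeros_like(logits, dtype=np.float32)
    loss = np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits)))
    p = 1.0 / (1.0 + np.exp(-logits))
    if weights is None:
        n = logits.size
        return float(loss.mean()), ((p - t) / n).astype(np.float32)
    w = np.asarray(weights, dtype=np.float64)
    n = w.sum()
    return float((w * loss).sum() / n), (w * (p - t) / n).astype(np.float32)


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0):
    """Mean smooth-L1 (Huber) loss: quadratic below ``beta``, linear above."""
    d = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    ad = np.abs(d)
    quad = ad < beta
    loss = np.where(quad, 0.5 * d * d / beta, ad - 0.5 * beta)
    grad = np.where(quad, d / beta, np.sign(d))
    n = max(pred.size, 1)
    return float(loss.mean()) if pred.size else 0.0, \
        (grad / n).astype(np.float32)
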