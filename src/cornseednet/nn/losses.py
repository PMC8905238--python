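"""Softmax probabilities and categorical cross-entropy.

The probability of sample i belonging to class m is

    y_im = exp(z_im) / sum_k exp(z_ik)

computed with max-subtraction for numerical stability, and the loss over a
batch of n samples with one-hot targets yhat is

    L = - sum_i  yhat_im * log(y_im)

with the natural logarithm (training behaviour is invariant to the log base
up to a constant factor in the learning rate).  ``reduction="mean"`` divides
by the batch size, which makes learning rates batch-size independent and is
what the trainer optimises.
"""

from __future__ import annotations

import numpy as np

PROB_FLOOR = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of finite scores; each output row sums to 1."""
    z = np.asarray(z, dtype=np.float64)
    squeeze = z.ndim == 1
    if squeeze:
        z = z[None, :]
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite scores")
    e = np.exp(z - z.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def cross_entropy(probs: np.ndarray, one_hot: np.ndarray, reduction: str = "sum") -> float:
    """Categorical cross-entropy of predicted ``probs`` against one-hot targets.

    Probabilities are clipped at 1e-12 before the log.  ``reduction`` is
    "sum" (the batch-sum form of the loss definition) or "mean".
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    one_hot = np.atleast_2d(np.asarray(one_hot, dtype=np.float64))
    if probs.shape != one_hot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {one_hot.shape}")
    ll = one_hot * np.log(np.clip(probs, PROB_FLOOR, 1.0))
    total = -ll.sum()
    if reduction == "sum":
        return float(total)
    if reduction == "mean":
        return float(total / probs.shape[0])
    raise ValueError(f"unknown reduction {reduction!r}")


class SoftmaxCrossEntropy:
    """Fused softmax + cross-entropy with the standard (p - y)/n gradient."""

    def forward(self, logits: np.ndarray, target_idx: np.ndarray) -> float:
        self._dtype = np.asarray(logits).dtype
        self.probs = softmax(logits)
        n = self.probs.shape[0]
        self.target_idx = np.asarray(target_idx)
        picked = self.probs[np.arange(n), self.target_idx]
        return float(-np.log(np.clip(picked, PROB_FLOOR, 1.0)).mean())

    def backward(self) -> np.ndarray:
        n = self.probs.shape[0]
        d = self.probs.copy()
        d[np.arange(n), self.target_idx] -= 1.0
        return (d / n).astype(self._dtype)
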