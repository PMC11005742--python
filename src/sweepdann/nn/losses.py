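"""Loss functions returning (value, gradient-w.r.t.-logits)."""

from __future__ import annotations

import numpy as np


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; labels are integer class indices."""
    p = softmax_probs(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy; logits shape (B, 1) or (B,)."""
    z = logits.reshape(-1)
    t = targets.reshape(-1).astype(float)
    p = sigmoid(z)
    loss = float(np.mean(-t * np.log(p + 1e-300) - (1 - t) * np.log(1 - p + 1e-300)))
    grad = ((p - t) / z.size).reshape(logits.shape)
    return loss, grad
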