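"""Loss functions returning (loss, dlogits) pairs, averaged over the batch."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax.

    Returns the scalar loss and the gradient with respect to ``logits``
    (already scaled by ``weight`` and the 1/N batch average).
    """
    n = logits.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    p = softmax(logits, axis=1)
    idx = (np.arange(n), labels)
    loss = -np.log(np.clip(p[idx], 1e-12, None)).mean() * weight
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    return float(loss), dlogits * (weight / n)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores (numerically stable form)."""
    n = logits.size
    if n == 0:
        raise ValueError("empty batch")
    z, t = logits, targets
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dlogits = (sigmoid(z) - t) * (weight / n)
    return float(loss.mean() * weight), dlogits


def mse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None,
             weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean squared (Euclidean) loss per coordinate, optionally masked per row.

    ``mask`` is a boolean row selector (e.g. positives only); masked-out rows
    contribute neither loss nor gradient. The average is taken over all
    contributing coordinates.
    """
    diff = pred - target
    if mask is not None:
        diff = diff * mask[:, None]
        denom = int(mask.sum()) * pred.shape[1]
    else:
        denom = diff.size
    if denom == 0:
        return 0.0, np.zeros_like(pred)
    loss = float((diff ** 2).sum() / denom) * weight
    return loss, diff * (2.0 * weight / denom)
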