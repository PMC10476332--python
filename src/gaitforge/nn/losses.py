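"""Loss functions returning (scalar loss, gradient w.r.t. predictions)."""

from __future__ import annotations

import numpy as np


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error over all elements."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / diff.size
    return loss, grad


def bce_with_logits(logits: np.ndarray, target: float):
    """Binary cross-entropy against a constant 0/1 label, on raw logits.

    The log-sum-exp form is numerically stable for large |logits|.
    """
    z = np.asarray(logits, dtype=float)
    y = float(target)
    # loss = max(z,0) - z*y + log(1+exp(-|z|))
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    sig = np.empty_like(z)
    pos = z >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    sig[~pos] = ez / (1.0 + ez)
    grad = (sig - y) / z.size
    return loss, grad
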