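"""Classification loss for the latent-patch classifier."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of 2-class (or k-class) logits.

    Returns ``(loss, grad_logits)`` where the gradient is with respect to the
    raw logits (softmax folded in analytically).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
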