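"""Loss and activation functionals."""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "cross_entropy"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch of integer class targets.

    Returns ``(loss, dlogits)`` with the gradient already averaged over
    the batch, ready to feed a model's ``backward``.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), targets] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(np.float32)
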