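"""Loss functions returning (scalar loss, gradient w.r.t. model output)."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def nll_from_probs(probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy taking class probabilities (post-softmax) directly.

    ``probs``: (n, k) rows on the simplex; ``targets``: (n,) int class ids.
    """
    n = probs.shape[0]
    p_t = np.clip(probs[np.arange(n), targets], _EPS, None)
    loss = float(-np.log(p_t).mean())
    grad = np.zeros_like(probs)
    grad[np.arange(n), targets] = -1.0 / (p_t * n)
    return loss, grad


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error over all elements."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad
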