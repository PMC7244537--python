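"""Loss functions and activations for the two U-nets.

The enhancement network minimizes a mean-absolute-error term plus a
total-variation regularizer; the segmentation network minimizes a
class-weighted softmax cross entropy in which normal red blood cells
carry twice the weight of background and sickle cells (to suppress
false positive sickle calls driven by class imbalance).

All images here are channel-last ``(..., M, N, C)`` or plain grids; the
training code converts as needed.  Every loss has a closed-form gradient
used by the manual backward pass.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.1
PROB_FLOOR = 1e-12  # clamp before log so an exactly-zero probability is finite
DEFAULT_CLASS_WEIGHTS = (1.0, 2.0, 1.0)  # background, normal, sickle


def leaky_relu(v: np.ndarray | float, slope: float = LEAKY_SLOPE):
    """Elementwise ``v`` where positive, ``slope * v`` otherwise."""
    v = np.asarray(v, dtype=float)
    return np.where(v > 0, v, slope * v)


def leaky_relu_grad(v: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(v > 0, 1.0, slope)


def _check_same_shape(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def l1_loss(z: np.ndarray, g: np.ndarray) -> float:
    """Mean absolute error between target ``z`` and network output ``g``."""
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    _check_same_shape(z, g)
    return float(np.mean(np.abs(g - z)))


def l1_loss_grad(z: np.ndarray, g: np.ndarray) -> np.ndarray:
    _check_same_shape(z, g)
    return np.sign(g - z) / g.size


def tv_loss(g: np.ndarray) -> float:
    """Anisotropic total variation, averaged over all pixels and channels.

    Forward differences are taken wherever the forward neighbor exists;
    the normalization stays the full pixel-channel count.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim == 2:
        g = g[..., None]
    dv = np.abs(g[1:, :, :] - g[:-1, :, :]).sum()
    dh = np.abs(g[:, 1:, :] - g[:, :-1, :]).sum()
    return float((dv + dh) / g.size)


def tv_loss_grad(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    squeeze = g.ndim == 2
    if squeeze:
        g = g[..., None]
    grad = np.zeros_like(g)
    sv = np.sign(g[1:, :, :] - g[:-1, :, :])
    grad[1:, :, :] += sv
    grad[:-1, :, :] -= sv
    sh = np.sign(g[:, 1:, :] - g[:, :-1, :])
    grad[:, 1:, :] += sh
    grad[:, :-1, :] -= sh
    grad /= g.size
    return grad[..., 0] if squeeze else grad


def enhancement_loss(z: np.ndarray, g: np.ndarray, lambda_tv: float = 0.03) -> float:
    """L1 reconstruction term plus ``lambda_tv`` times the TV regularizer."""
    if lambda_tv < 0:
        raise ValueError("lambda_tv must be >= 0")
    return l1_loss(z, g) + lambda_tv * tv_loss(g)


def enhancement_loss_grad(z, g, lambda_tv: float = 0.03) -> np.ndarray:
    return l1_loss_grad(z, g) + lambda_tv * tv_loss_grad(g)


def softmax_probs(y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-pixel softmax over the class axis, max-stabilized."""
    y = np.asarray(y, dtype=float)
    shifted = y - y.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("mask contains labels outside the class range")
    return np.eye(n_classes)[mask]


def weighted_ce_loss(
    a: np.ndarray,
    p: np.ndarray,
    weights=DEFAULT_CLASS_WEIGHTS,
) -> float:
    """Class-weighted cross entropy between one-hot labels and probabilities.

    ``a`` and ``p`` are ``(M, N, C)`` (or any leading shape ending in the
    class axis).  The normalization is the number of pixels (not pixels
    times channels).  Probabilities are clamped at ``PROB_FLOOR`` before
    the log.
    """
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    _check_same_shape(a, p)
    if not np.allclose(a.sum(axis=-1), 1.0) or not np.all((a == 0) | (a == 1)):
        raise ValueError("labels must be one-hot")
    w = np.asarray(weights, dtype=float)
    n_pixels = a.size // a.shape[-1]
    logp = np.log(np.clip(p, PROB_FLOOR, None))
    return float(-(a * logp * w).sum() / n_pixels)


def weighted_ce_from_logits(a, y, weights=DEFAULT_CLASS_WEIGHTS) -> float:
    return weighted_ce_loss(a, softmax_probs(y), weights)


def weighted_ce_logits_grad(a, y, weights=DEFAULT_CLASS_WEIGHTS) -> np.ndarray:
    """Gradient of the weighted cross entropy w.r.t. the logits ``y``.

    With one-hot ``a``, the pixel's true-class weight scales the usual
    ``softmax - onehot`` term.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = softmax_probs(y)
    w_true = (a * w).sum(axis=-1, keepdims=True)
    n_pixels = a.size // a.shape[-1]
    return w_true * (p - a) / n_pixels
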