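"""Training losses: focal classification loss and top-k pixel cross-entropy.

Both operate on *unnormalized* scores (logits); the softmax lives inside the
loss for numerical stability.  Gradients are returned analytically because
the network backend has no autodiff.

Focal loss: ``FL = -alpha_y * (1 - p_y)^gamma * log p_y`` with
``p = softmax(scores)``; gamma=0, alpha=1 reduces to plain cross-entropy.

Top-k cross-entropy: per-pixel CE is computed over the class axis, the
``k = ceil(topk_fraction * n_pixels)`` largest per-pixel losses (per image)
are averaged, and gradients flow only through those k pixels.  Ties at the
k-th value are broken by a stable descending sort, keeping the first k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LossConfig

_EPS = 1e-12


def _softmax(scores: np.ndarray, axis: int) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _log_softmax(scores: np.ndarray, axis: int) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def _alpha_vector(config: LossConfig, n_classes: int) -> np.ndarray:
    if config.focal_alpha is None:
        return np.ones(n_classes)
    alpha = np.asarray(config.focal_alpha, dtype=float)
    if alpha.shape != (n_classes,):
        raise ValueError(f"focal_alpha must have {n_classes} entries")
    return alpha


def focal_loss(cls_scores: np.ndarray, labels, config: LossConfig) -> float:
    """Mean focal loss over a batch of class score vectors."""
    loss, _ = focal_loss_with_grad(cls_scores, labels, config)
    return loss


def focal_loss_with_grad(cls_scores, labels, config: LossConfig):
    """Return (mean loss, gradient w.r.t. scores)."""
    scores = np.atleast_2d(np.asarray(cls_scores, dtype=float))
    y = np.atleast_1d(np.asarray(labels, dtype=int))
    n, c = scores.shape
    if y.shape != (n,):
        raise ValueError("labels do not match batch size")
    if np.any((y < 0) | (y >= c)):
        raise ValueError("label outside valid class range")
    alpha = _alpha_vector(config, c)[y]  # (n,)
    gamma = config.focal_gamma

    p = _softmax(scores, axis=1)
    logp = _log_softmax(scores, axis=1)
    idx = np.arange(n)
    py = np.clip(p[idx, y], _EPS, 1.0)
    logpy = logp[idx, y]
    one_m = 1.0 - p[idx, y]
    loss = float(np.mean(-alpha * one_m**gamma * logpy))

    # dL/dpy, then chain through softmax: dpy/dz_j = py*(delta_jy - p_j)
    if gamma == 0:
        dl_dpy = -alpha / py
    else:
        dl_dpy = alpha * (gamma * one_m ** (gamma - 1) * logpy - one_m**gamma / py)
    grad = p * (dl_dpy * py)[:, None] * (-1.0)
    grad[idx, y] += dl_dpy * py
    grad /= n
    if np.asarray(cls_scores).ndim == 1:
        grad = grad[0]
    return loss, grad


def topk_cross_entropy(seg_scores: np.ndarray, mask: np.ndarray, config: LossConfig) -> float:
    """Mean over images of the average CE of each image's k worst pixels."""
    loss, _ = topk_cross_entropy_with_grad(seg_scores, mask, config)
    return loss


def topk_cross_entropy_with_grad(seg_scores, mask, config: LossConfig):
    """Return (loss, gradient w.r.t. seg_scores).

    ``seg_scores``: (C, H, W) or (N, C, H, W); ``mask``: matching (H, W) /
    (N, H, W) integer class targets (binary masks are class indices already).
    """
    scores = np.asarray(seg_scores, dtype=float)
    single = scores.ndim == 3
    if single:
        scores = scores[None]
    targets = np.asarray(mask).astype(int)
    if single and targets.ndim == 2:
        targets = targets[None]
    n, c, h, w = scores.shape
    if targets.shape != (n, h, w):
        raise ValueError(
            f"mask shape {targets.shape} incompatible with scores {scores.shape}"
        )
    n_pixels = h * w
    k = int(np.ceil(config.topk_fraction * n_pixels))

    logp = _log_softmax(scores, axis=1)  # (n, c, h, w)
    flat_t = targets.reshape(n, n_pixels)
    flat_logp = logp.reshape(n, c, n_pixels)
    ce = -np.take_along_axis(flat_logp, flat_t[:, None, :], axis=1)[:, 0, :]  # (n, px)

    # stable descending order; keep first k per image
    order = np.argsort(-ce, axis=1, kind="stable")[:, :k]
    sel = np.zeros((n, n_pixels), dtype=bool)
    np.put_along_axis(sel, order, True, axis=1)
    loss = float(np.take_along_axis(ce, order, axis=1).mean())

    p = np.exp(flat_logp)  # (n, c, px)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, flat_t[:, None, :], 1.0, axis=1)
    grad = (p - onehot) * sel[:, None, :] / (k * n)
    grad = grad.reshape(n, c, h, w)
    if single:
        grad = grad[0]
    return loss, grad


@dataclass
class CombinedLoss:
    total: float
    seg: float
    cls: float


def combined_loss(output, mask, label, config: LossConfig) -> CombinedLoss:
    """Equally balanced (by default) sum of the two task losses."""
    res, _, _ = combined_loss_with_grads(
        output.seg_scores, output.cls_scores, mask, label, config
    )
    return res


def combined_loss_with_grads(seg_scores, cls_scores, mask, label, config: LossConfig):
    """Return (CombinedLoss, d/d seg_scores, d/d cls_scores)."""
    seg, dseg = topk_cross_entropy_with_grad(seg_scores, mask, config)
    cls, dcls = focal_loss_with_grad(cls_scores, label, config)
    total = config.seg_weight * seg + config.cls_weight * cls
    return (
        CombinedLoss(total=total, seg=seg, cls=cls),
        config.seg_weight * dseg,
        config.cls_weight * dcls,
    )
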