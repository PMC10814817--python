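"""Losses on logits, each returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

from typing import Tuple

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def mse_loss(logits: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error between sigmoid(logits) and target in [0, 1]."""
    p = sigmoid(logits)
    diff = p - target
    loss = float(np.mean(diff**2))
    dz = (2.0 / diff.size) * diff * p * (1.0 - p)
    return loss, dz.astype(np.float32)


def bce_loss(logits: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Binary cross-entropy, numerically stable on logits."""
    z, t = logits, target
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - t) / z.size
    return loss, dz.astype(np.float32)


def _dice_loss(p: np.ndarray, t: np.ndarray, smooth: float = 1.0) -> Tuple[float, np.ndarray]:
    # soft Dice per (sample, channel), averaged
    n, c = p.shape[:2]
    pf = p.reshape(n * c, -1)
    tf = t.reshape(n * c, -1)
    inter = (pf * tf).sum(axis=1)
    denom = pf.sum(axis=1) + tf.sum(axis=1) + smooth
    dice = (2.0 * inter + smooth) / denom
    loss = float(np.mean(1.0 - dice))
    # d(1 - dice)/dp = (dice - 2 t) / denom  (per sample-channel)
    dp = (dice[:, None] - 2.0 * tf) / denom[:, None] / (n * c)
    return loss, dp.reshape(p.shape).astype(np.float32)


def bce_dice_loss(logits: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """BCE + soft Dice, the default segmentation loss for stages 2-3."""
    bce, dz_bce = bce_loss(logits, target)
    p = sigmoid(logits)
    dice, dp = _dice_loss(p, target)
    dz = dz_bce + dp * p * (1.0 - p)
    return bce + dice, dz.astype(np.float32)


LOSSES = {"mse": mse_loss, "bce": bce_loss, "bce_dice": bce_dice_loss}
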