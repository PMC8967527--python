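"""Dice-loss training loop shared by both segmentation networks."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Module
from .optim import Adam


def train_dice(net: Module, images: np.ndarray, masks: np.ndarray, *,
               epochs: int = 30, lr: float = 1e-3, batch_size: int = 8,
               seed: int = 0) -> list[float]:
    """Minimise the Dice loss of ``net`` on (image, mask) pairs.

    ``images``/``masks`` are (N, H, W) arrays; images should already be
    intensity-normalised to roughly [0, 1]. Returns the per-epoch mean
    loss history. A fixed seed makes the shuffling — and hence the whole
    run — reproducible on one machine.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if len(images) == 0:
        raise ValueError("no training pairs supplied")
    if images.shape != masks.shape:
        raise ValueError("images and masks must have identical shapes")
    if not masks.any():
        raise ValueError("all masks are background; nothing to learn")
    rng = np.random.default_rng(seed)
    params = net.parameters()
    opt = Adam(params, lr=lr)
    history: list[float] = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(images[idx][:, None])  # (B,1,H,W)
            y = masks[idx][:, None]
            p = net(x)
            loss = ag.soft_dice_loss(p, y)
            losses.append(float(loss.data))
            if lr > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
        history.append(float(np.mean(losses)))
    return history


def predict_batched(net: Module, images: np.ndarray,
                    batch_size: int = 16) -> np.ndarray:
    """Run inference on (N, H, W) images; returns (N, H, W) probabilities."""
    images = np.asarray(images, dtype=np.float32)
    outs = []
    for start in range(0, len(images), batch_size):
        x = Tensor(images[start:start + batch_size][:, None])
        outs.append(net(x).data[:, 0])
    return np.concatenate(outs, axis=0)
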