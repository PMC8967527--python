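"""Attention-gated U-Net for lung-parenchyma segmentation.

The network is an encoder–decoder with three architecture elements
beyond plain U-Net:

* **Attention gates** on every skip connection. With encoder feature x
  and decoder (gating) feature g, the gate computes
  ``α = σ2(φᵀ σ1(W_xᵀx + W_gᵀg + b_g))`` with σ1 = ReLU and σ2 the
  logistic sigmoid, and passes ``α ⊙ x`` forward; α ∈ (0,1) weights the
  encoder feature towards the region the coarser decoder context finds
  relevant.
* A **dense atrous convolution (DAC) bottleneck**: four cascaded
  branches of stacked 3×3 dilated convolutions (dilations from {1,3,5})
  with effective receptive fields 3, 7, 9 and 19, summed together with
  the residual input.
* **Multiscale sampling blocks**: every scale change runs parallel
  (transposed) convolutions of distinct kernel sizes whose outputs are
  added, instead of pooling/single deconvolution.

Training minimises the Dice loss (see ``nodulekit.nn.train``).
"""

from __future__ import annotations

import json
import os

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Conv2d, ConvBlock, Module, MultiScaleDown,
                        MultiScaleUp, ReLU, Sequential)
from .nn.train import predict_batched, train_dice

#: (kernel, dilation) stacks of the four DAC cascade branches; their
#: receptive fields are 3, 7, 9 and 19.
DAC_BRANCHES: tuple[tuple[tuple[int, int], ...], ...] = (
    ((3, 1),),
    ((3, 3), (1, 1)),
    ((3, 1), (3, 3), (1, 1)),
    ((3, 1), (3, 3), (3, 5), (1, 1)),
)


def receptive_field(branch) -> int:
    """Effective receptive field of stacked stride-1 convolutions.

    For (kernel, dilation) pairs: RF = 1 + Σ dᵢ·(kᵢ − 1). Kernels must
    be odd and dilations ≥ 1; an empty branch sees a single pixel.
    """
    rf = 1
    for k, d in branch:
        if k % 2 == 0:
            raise ValueError(f"kernel sizes must be odd, got {k}")
        if d < 1:
            raise ValueError(f"dilations must be >= 1, got {d}")
        rf += d * (k - 1)
    return rf


class AttentionGate(Module):
    """Additive attention gate producing α ∈ (0,1) and returning α ⊙ x."""

    def __init__(self, channels: int, inter_channels: int, rng):
        self.wx = Conv2d(channels, inter_channels, 1, rng, bias=False)
        self.wg = Conv2d(channels, inter_channels, 1, rng, bias=True)
        self.phi = Conv2d(inter_channels, 1, 1, rng, bias=True)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        if x.shape[1] != self.wx.weight.shape[1]:
            raise ValueError(
                f"attention gate expects {self.wx.weight.shape[1]} channels, "
                f"got {x.shape[1]}")
        alpha = self.attention(x, g)
        return alpha * x

    def attention(self, x: Tensor, g: Tensor) -> Tensor:
        """The attention coefficient map α, shape (N, 1, H, W)."""
        if x.shape[2:] != g.shape[2:]:
            raise ValueError("x and g must be spatially compatible")
        return ag.sigmoid(self.phi(ag.relu(self.wx(x) + self.wg(g))))

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        return self.forward(x, g)


def attention_gate(x, g, gate: AttentionGate):
    """Functional form: apply a configured attention gate to (x, g)."""
    xt = x if isinstance(x, Tensor) else Tensor(x)
    gt = g if isinstance(g, Tensor) else Tensor(g)
    return gate(xt, gt)


class DACBlock(Module):
    """Dense atrous convolution block (four cascade branches + residual)."""

    def __init__(self, channels: int, rng, branches=DAC_BRANCHES):
        self.branches = []
        for branch in branches:
            mods = []
            for k, d in branch:
                mods += [Conv2d(channels, channels, k, rng, dilation=d), ReLU()]
            self.branches.append(Sequential(*mods[:-1]))  # no ReLU after last
        self.rf = tuple(receptive_field(b) for b in branches)

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for branch in self.branches:
            out = out + branch(x)
        return ag.relu(out)


class AttentionUNet(Module):
    """Encoder–decoder with attention-gated skips and a DAC bottleneck.

    ``pad_policy='auto'`` edge-pads any input whose spatial size is not
    divisible by 2^(levels−1) and crops the output back, so the output
    probability map always matches the input size; ``'strict'`` raises
    instead, naming the padding that would be required.
    """

    def __init__(self, levels: int = 4, base_channels: int = 16,
                 in_channels: int = 1, seed: int = 0,
                 pad_policy: str = "auto"):
        if levels < 2:
            raise ValueError("levels must be >= 2")
        if pad_policy not in ("auto", "strict"):
            raise ValueError("pad_policy must be 'auto' or 'strict'")
        self.config = {"levels": levels, "base_channels": base_channels,
                       "in_channels": in_channels, "seed": seed,
                       "pad_policy": pad_policy}
        self.levels = levels
        self.pad_policy = pad_policy
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**i for i in range(levels)]
        self.enc = [ConvBlock(in_channels if i == 0 else ch[i], ch[i], rng)
                    for i in range(levels)]
        self.down = [MultiScaleDown(ch[i], ch[i + 1], rng)
                     for i in range(levels - 1)]
        self.dac = DACBlock(ch[-1], rng)
        self.up = [MultiScaleUp(ch[i + 1], ch[i], rng)
                   for i in reversed(range(levels - 1))]
        self.gates = [AttentionGate(ch[i], max(ch[i] // 2, 1), rng)
                      for i in reversed(range(levels - 1))]
        self.dec = [ConvBlock(2 * ch[i], ch[i], rng)
                    for i in reversed(range(levels - 1))]
        self.head = Conv2d(ch[0], 1, 1, rng)
        # start the output near a low foreground prior: avoids the
        # all-background collapse mode of the Dice loss on small targets
        self.head.bias.data[:] = -2.0

    def forward(self, x: Tensor) -> Tensor:
        x, crop = _pad_to_multiple(x, 2 ** (self.levels - 1), self.pad_policy)
        skips = []
        h = x
        for i in range(self.levels - 1):
            h = self.enc[i](h)
            skips.append(h)
            h = self.down[i](h)
        h = self.enc[-1](h)
        h = self.dac(h)
        for up, gate, dec, skip in zip(self.up, self.gates, self.dec,
                                       reversed(skips)):
            g = up(h)
            h = dec(ag.concat([gate(skip, g), g], axis=1))
        out = ag.sigmoid(self.head(h))
        if crop is not None:
            out = ag.crop2d(out, 0, 0, crop[0], crop[1])
        return out


def _pad_to_multiple(x: Tensor, mult: int, policy: str):
    n, c, h, w = x.shape
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return x, None
    if policy == "strict":
        raise ValueError(
            f"input {h}×{w} is not divisible by {mult}; pad to "
            f"{h + ph}×{w + pw} (e.g. {ph} rows / {pw} columns of edge padding)")
    padded = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
    return Tensor(padded, requires_grad=False), (h, w)


def build_parenchyma_net(levels: int = 4, base_channels: int = 16,
                         seed: int = 0, pad_policy: str = "auto") -> AttentionUNet:
    """Construct the attention-gated parenchyma segmentation network."""
    return AttentionUNet(levels=levels, base_channels=base_channels,
                         seed=seed, pad_policy=pad_policy)


def train_segmenter(net: Module, slices: np.ndarray, masks: np.ndarray, *,
                    epochs: int = 30, lr: float = 1e-3, batch_size: int = 8,
                    seed: int = 0) -> list[float]:
    """Train a segmentation network with Dice loss; returns loss history.

    ``slices`` must already be intensity-normalised to [0, 1]
    (``volio.normalize_hu``); ``masks`` are binary.
    """
    return train_dice(net, slices, masks, epochs=epochs, lr=lr,
                      batch_size=batch_size, seed=seed)


def predict_slices(net: Module, slices: np.ndarray,
                   batch_size: int = 16) -> np.ndarray:
    """Probability maps for a stack of normalised slices."""
    return predict_batched(net, slices, batch_size=batch_size)


# -- checkpoints -------------------------------------------------------

def save_checkpoint(net, path: str | os.PathLike) -> None:
    """Single-file .npz checkpoint with the build config embedded."""
    arrays = {f"p{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez_compressed(os.fspath(path), config=json.dumps(net.config),
                        **arrays)


def load_checkpoint(path: str | os.PathLike, builder=None):
    if not os.path.exists(os.fspath(path)):
        raise FileNotFoundError(f"checkpoint not found: {os.fspath(path)}")
    with np.load(os.fspath(path), allow_pickle=False) as data:
        config = json.loads(str(data["config"]))
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    if builder is None:
        builder = AttentionUNet
    net = builder(**config)
    net.load_state_arrays(arrays)
    return net
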