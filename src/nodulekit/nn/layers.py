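"""Layer/module abstractions over the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: children are discovered from instance attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    if id(v) not in seen:
                        seen.add(id(v))
                        params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1-by-default 2D convolution with 'same' padding for odd kernels."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, *,
                 stride: int = 1, dilation: int = 1, padding: int | None = None,
                 bias: bool = True):
        if padding is None:
            if stride != 1:
                raise ValueError("explicit padding required for strided conv")
            padding = dilation * (kernel - 1) // 2
        self.stride, self.dilation, self.padding = stride, dilation, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         dilation=self.dilation, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, *,
                 stride: int = 2, padding: int = 0, bias: bool = True):
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_he_init(rng, (in_ch, out_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias,
                                   stride=self.stride, padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Mish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.mish(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvBlock(Module):
    """Two 3×3 convolutions, each followed by the chosen activation."""

    def __init__(self, in_ch: int, out_ch: int, rng, activation: str = "relu"):
        act = {"relu": ReLU, "mish": Mish}[activation]
        self.net = Sequential(
            Conv2d(in_ch, out_ch, 3, rng), act(),
            Conv2d(out_ch, out_ch, 3, rng), act(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class MultiScaleDown(Module):
    """Halve spatial size via parallel strided convolutions of distinct
    kernel sizes (2 and 4) whose outputs are summed."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.c2 = Conv2d(in_ch, out_ch, 2, rng, stride=2, padding=0)
        self.c4 = Conv2d(in_ch, out_ch, 4, rng, stride=2, padding=1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(x) + self.c4(x)


class MultiScaleUp(Module):
    """Double spatial size via parallel transposed convolutions of
    distinct kernel sizes (2 and 4) whose outputs are summed."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.t2 = ConvTranspose2d(in_ch, out_ch, 2, rng, stride=2, padding=0)
        self.t4 = ConvTranspose2d(in_ch, out_ch, 4, rng, stride=2, padding=1,
                                  bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.t2(x) + self.t4(x)


class FastFusion(Module):
    """Weighted feature fusion with fast normalized nonnegative weights
    w_i = relu(u_i) / (Σ_j relu(u_j) + ε)."""

    def __init__(self, n_inputs: int, eps: float = 1e-4):
        self.raw = Tensor(np.ones(n_inputs, np.float32), requires_grad=True)
        self.eps = eps

    def weights(self) -> Tensor:
        pos = ag.relu(self.raw)
        total = ag.tsum(pos) + Tensor(self.eps)
        return pos / total

    def forward(self, inputs: list[Tensor]) -> Tensor:
        w = self.weights()
        out = ag.index(w, 0) * inputs[0]
        for i, f in enumerate(inputs[1:], start=1):
            out = out + ag.index(w, i) * f
        return out

    def __call__(self, inputs: list[Tensor]) -> Tensor:
        return self.forward(inputs)
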