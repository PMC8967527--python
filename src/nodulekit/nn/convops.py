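"""Raw NumPy 2D convolution kernels (forward and both backward passes).

Layout is NCHW for activations and (C_out, C_in, kh, kw) for weights.
The implementation extracts sliding windows with stride tricks and
contracts them with a single BLAS call (``tensordot``); the input
gradient is computed as a stride-1 convolution of the zero-stuffed
output gradient with the spatially flipped, channel-transposed kernel,
which keeps every pass on the same fast path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _windows(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
             padding: int) -> np.ndarray:
    """Return view (N, C, OH, OW, kh, kw) of sliding windows."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    if x.shape[2] < kh_eff or x.shape[3] < kw_eff:
        raise ValueError(
            f"input spatial size {x.shape[2:]} smaller than effective kernel "
            f"({kh_eff}, {kw_eff})")
    sw = sliding_window_view(x, (kh_eff, kw_eff), axis=(2, 3))
    return sw[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d(x: np.ndarray, w: np.ndarray, *, stride: int = 1,
           dilation: int = 1, padding: int = 0) -> np.ndarray:
    sw = _windows(x, w.shape[2], w.shape[3], stride, dilation, padding)
    out = np.tensordot(sw, w, axes=((1, 4, 5), (1, 2, 3)))
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d_bwd_input(gy: np.ndarray, w: np.ndarray, in_hw, *, stride: int,
                     dilation: int, padding: int) -> np.ndarray:
    """Gradient w.r.t. the conv input; doubles as transposed-conv forward.

    ``w`` is the conv weight (C_out, C_in, kh, kw); ``gy`` has C_out
    channels; the result has C_in channels and spatial size ``in_hw``.
    """
    n, co, oh, ow = gy.shape
    h, wd = in_hw
    kh, kw = w.shape[2], w.shape[3]
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    up_h = h + 2 * padding - kh_eff + 1
    up_w = wd + 2 * padding - kw_eff + 1
    if stride == 1:
        gy_up = gy
        if (up_h, up_w) != (oh, ow):
            raise ValueError("inconsistent gradient/input geometry")
    else:
        gy_up = np.zeros((n, co, up_h, up_w), dtype=gy.dtype)
        gy_up[:, :, ::stride, ::stride] = gy
    w_flip = np.ascontiguousarray(
        w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    return conv2d(gy_up, w_flip, stride=1, dilation=dilation,
                  padding=kh_eff - 1 - padding)


def conv2d_bwd_weight(x: np.ndarray, gy: np.ndarray, w_shape, *, stride: int,
                      dilation: int, padding: int) -> np.ndarray:
    co, ci, kh, kw = w_shape
    sw = _windows(x, kh, kw, stride, dilation, padding)
    gw = np.tensordot(gy, sw, axes=((0, 2, 3), (0, 2, 3)))
    return np.ascontiguousarray(gw)
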