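"""Multiposition (2.5D) reslicing, slice-size normalization and fusion.

A 3D volume indexed (z, y, x) is viewed as three stacks of 2D slices:
axial (fixed z), coronal (fixed y) and sagittal (fixed x). A sphere
looks round in every stack while a tube looks round only along its own
axis and like a long strip in the others — that asymmetry is what lets
the multiposition rule separate nodules from vessels. Reslicing is a
lossless bijection: stacking a position's slices back reproduces the
volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .volio import CTVolume

POSITIONS = ("axial", "coronal", "sagittal")

# (z,y,x) volume axis that each position's slice index runs along
_FIXED_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}
# transpose taking (z,y,x) to (slice, row, col) for each position
_TO_STACK = {"axial": (0, 1, 2), "coronal": (1, 0, 2), "sagittal": (2, 0, 1)}
_FROM_STACK = {p: tuple(np.argsort(t)) for p, t in _TO_STACK.items()}


@dataclass
class PositionStack:
    """An ordered sequence of 2D slices from one anatomical position,
    with the bookkeeping needed to invert the reslicing."""

    position: str
    slices: np.ndarray  # (n_slices, rows, cols)
    index_map: np.ndarray  # slice index -> plane coordinate in the volume
    original_size: tuple[int, int]

    def __len__(self) -> int:
        return self.slices.shape[0]


def reslice(volume: CTVolume | np.ndarray, position: str) -> PositionStack:
    """Exact planar sections of the volume in the given position."""
    if position not in POSITIONS:
        raise ValueError(f"position must be one of {POSITIONS}, got {position!r}")
    v = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    if v.ndim != 3 or v.size == 0:
        raise ValueError("volume must be a nonempty 3D array")
    slices = v.transpose(_TO_STACK[position])
    return PositionStack(
        position=position,
        slices=slices,
        index_map=np.arange(slices.shape[0]),
        original_size=slices.shape[1:],
    )


def stack(position_stack: PositionStack) -> np.ndarray:
    """Inverse of :func:`reslice`: reassemble the 3D volume."""
    return position_stack.slices.transpose(_FROM_STACK[position_stack.position])


def stack_array(slices: np.ndarray, position: str) -> np.ndarray:
    """Reassemble raw (n, rows, cols) slices (e.g. predictions) to 3D."""
    return np.asarray(slices).transpose(_FROM_STACK[position])


def normalize_slice(image: np.ndarray, target: tuple[int, int] = (200, 200)) -> np.ndarray:
    """Bilinear resize of one slice to the working size (default 200×200).

    Returns the input unchanged (same object semantics, copied) when it
    already has the target size; :func:`denormalize_slice` maps
    predictions back to the original geometry.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    if image.shape == tuple(target):
        return image.copy()
    return resize(image.astype(np.float32), target, order=1,
                  preserve_range=True, anti_aliasing=False)


def denormalize_slice(image: np.ndarray, original_size: tuple[int, int]) -> np.ndarray:
    return normalize_slice(image, tuple(original_size))


def fuse_position_masks(axial: np.ndarray, coronal: np.ndarray,
                        sagittal: np.ndarray, rule: str = "majority") -> np.ndarray:
    """Voxelwise combination of three reassembled 3D position masks.

    ``majority`` keeps voxels positive in ≥2 of 3 positions (the default:
    one position alone is not trusted), ``union`` in ≥1, ``intersection``
    in all 3.
    """
    masks = [np.asarray(m, bool) for m in (axial, coronal, sagittal)]
    if not (masks[0].shape == masks[1].shape == masks[2].shape):
        raise ValueError("the three masks must have identical 3D shapes")
    votes = sum(m.astype(np.uint8) for m in masks)
    if rule == "majority":
        return votes >= 2
    if rule == "union":
        return votes >= 1
    if rule == "intersection":
        return votes == 3
    raise ValueError(f"unknown fusion rule {rule!r}")
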