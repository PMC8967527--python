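"""Multiposition nodule segmentation with a bidirectional feature
pyramid U-Net and circularity screening.

Per position (axial/coronal/sagittal) a same-size U-Net — edge padding
instead of cropping, so output size equals input size — encodes five
resolution levels, fuses them with a bidirectional (top-down then
bottom-up) feature pyramid using fast normalized fusion weights, and
emits a per-pixel nodule probability map. Activations are Mish,
f(x) = x·tanh(ln(1+eˣ)): smooth, nonmonotonic, and letting a small
negative signal pass where ReLU would cut the gradient.

The three thresholded position masks are reassembled to 3D, fused by
majority vote, and the connected components are screened: a candidate
is kept when its equivalent diameter is in the working range and the
maximum-area cross-section is sufficiently circular (4πA/P²) in at
least two of the three positions. A vessel tube is round in one
position only, so the screen rejects it while keeping spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from . import multiview, volio
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv2d, ConvBlock, FastFusion, Module, MultiScaleDown
from .nn.train import predict_batched
from .parenchyma import _pad_to_multiple


def mish(x):
    """Mish activation x·tanh(softplus(x)) on scalars or arrays.

    Uses the overflow-free softplus ``max(x,0) + log1p(exp(-|x|))``.
    """
    x = np.asarray(x, dtype=np.float64)
    sp = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = x * np.tanh(sp)
    return float(out) if out.ndim == 0 else out


@dataclass
class NoduleNetConfig:
    levels: int = 5
    base_channels: int = 8
    pyramid_channels: int = 16
    in_channels: int = 1
    seed: int = 0
    pad_policy: str = "auto"
    prob_threshold: float = 0.5
    fusion_rule: str = "majority"
    min_circularity: float = 0.55
    diam_range_mm: tuple[float, float] = (4.0, 12.0)

    def __post_init__(self):
        if self.levels < 3:
            raise ValueError("levels must be >= 3")


class BiFPNUNet(Module):
    """Same-size U-Net with bidirectional enhanced feature pyramid."""

    def __init__(self, levels: int = 5, base_channels: int = 8,
                 pyramid_channels: int = 16, in_channels: int = 1,
                 seed: int = 0, pad_policy: str = "auto"):
        if levels < 3:
            raise ValueError("levels must be >= 3 (5 is the working depth)")
        self.config = {"levels": levels, "base_channels": base_channels,
                       "pyramid_channels": pyramid_channels,
                       "in_channels": in_channels, "seed": seed,
                       "pad_policy": pad_policy}
        self.levels = levels
        self.pad_policy = pad_policy
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**min(i, 3) for i in range(levels)]
        w = pyramid_channels
        self.enc = [ConvBlock(in_channels if i == 0 else ch[i], ch[i],
                              rng, activation="mish") for i in range(levels)]
        self.down = [MultiScaleDown(ch[i], ch[i + 1], rng)
                     for i in range(levels - 1)]
        self.proj = [Conv2d(ch[i], w, 1, rng) for i in range(levels)]
        # top-down pass: one fusion node per level below the top
        self.td_fuse = [FastFusion(2) for _ in range(levels - 1)]
        self.td_conv = [Conv2d(w, w, 3, rng) for _ in range(levels - 1)]
        # bottom-up path augmentation: one node per level above the bottom
        self.bu_fuse = [FastFusion(3) for _ in range(levels - 1)]
        self.bu_conv = [Conv2d(w, w, 3, rng) for _ in range(levels - 1)]
        self.head = Conv2d(w, 1, 1, rng)
        # low-foreground-prior head bias: guards the Dice loss against
        # collapsing to all-background on small nodule targets
        self.head.bias.data[:] = -2.0

    def forward(self, x: Tensor) -> Tensor:
        if min(x.shape[2], x.shape[3]) < 2 ** (self.levels - 1):
            raise ValueError(
                f"input {x.shape[2]}×{x.shape[3]} too small for "
                f"{self.levels - 1} halvings; minimum size is "
                f"{2 ** (self.levels - 1)}")
        x, crop = _pad_to_multiple(x, 2 ** (self.levels - 1), self.pad_policy)
        feats = []
        h = x
        for i in range(self.levels):
            h = self.enc[i](h)
            feats.append(self.proj[i](h))
            if i < self.levels - 1:
                h = self.down[i](h)
        # top-down: coarse context flows to fine levels
        td = [None] * self.levels
        td[-1] = feats[-1]
        for i in range(self.levels - 2, -1, -1):
            up = ag.upsample_nearest2x(td[i + 1])
            td[i] = ag.mish(self.td_conv[i](
                self.td_fuse[i]([feats[i], up])))
        # bottom-up path enhancement: fine localisation flows back up
        bu = [None] * self.levels
        bu[0] = td[0]
        for i in range(1, self.levels):
            down = ag.avgpool2x(bu[i - 1])
            bu[i] = ag.mish(self.bu_conv[i - 1](
                self.bu_fuse[i - 1]([feats[i], td[i], down])))
        out = ag.sigmoid(self.head(bu[0]))
        if crop is not None:
            out = ag.crop2d(out, 0, 0, crop[0], crop[1])
        return out


def build_nodule_net(cfg: NoduleNetConfig | None = None, **kwargs) -> BiFPNUNet:
    """Construct the bidirectional-feature-pyramid nodule network."""
    if cfg is None:
        cfg = NoduleNetConfig(**kwargs)
    return BiFPNUNet(levels=cfg.levels, base_channels=cfg.base_channels,
                     pyramid_channels=cfg.pyramid_channels,
                     in_channels=cfg.in_channels, seed=cfg.seed,
                     pad_policy=cfg.pad_policy)


# -- circularity and screening ----------------------------------------

def circularity(region: np.ndarray) -> float:
    """4π·Area/Perimeter² of a 2D binary region, clamped to [0, 1].

    The perimeter is the arc length of the subpixel iso-0.5 contour
    (marching squares), which is unbiased enough that an ideal disc
    scores ≈ 1; a naive pixel-edge count would overshoot. Multi-contour
    regions use the total contour length.
    """
    region = np.asarray(region, bool)
    if not region.any():
        raise ValueError("circularity of an empty region is undefined")
    area = float(region.sum())
    padded = np.pad(region.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    perim = sum(
        float(np.sqrt(((c[1:] - c[:-1]) ** 2).sum(axis=1)).sum())
        for c in contours)
    if perim == 0:  # single isolated pixel
        return 1.0
    return float(min(4.0 * np.pi * area / perim**2, 1.0))


@dataclass
class NoduleCandidate:
    """A 26-connected 3D component with its per-position evidence."""

    component_id: int
    voxel_count: int
    centroid_voxel: tuple[float, float, float]
    centroid_mm: tuple[float, float, float]
    equivalent_diameter_mm: float
    circularity: dict[str, float]
    profiles: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    accepted: bool = False
    features: dict[str, float] | None = None
    mask: np.ndarray | None = field(repr=False, default=None)

    def to_json(self) -> dict:
        return {
            "component_id": self.component_id,
            "voxel_count": self.voxel_count,
            "centroid_mm": list(self.centroid_mm),
            "equivalent_diameter_mm": self.equivalent_diameter_mm,
            "circularity": self.circularity,
            "accepted": bool(self.accepted),
        }


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def max_area_slice(mask: np.ndarray, position: str) -> np.ndarray:
    """The 2D cross-section of largest area in the given position."""
    stack = multiview.reslice(mask, position).slices
    areas = stack.reshape(len(stack), -1).sum(axis=1)
    return stack[int(np.argmax(areas))].astype(bool)


def screen_candidates(mask3d: np.ndarray, spacing, *,
                      min_circ: float = 0.55,
                      diam_range_mm: tuple[float, float] = (4.0, 12.0),
                      keep_rejected: bool = False) -> list[NoduleCandidate]:
    """Score 26-connected components and keep nodule-like ones.

    A component is accepted iff its equivalent spherical diameter lies in
    ``diam_range_mm`` and the circularity of its maximum-area slice is
    ≥ ``min_circ`` in at least two of the three positions. Raising
    ``min_circ`` can only shrink the accepted set.
    """
    mask3d = np.asarray(mask3d, bool)
    spacing = tuple(float(s) for s in spacing)
    if not mask3d.any():
        return []
    labels, n = ndimage.label(mask3d, structure=_STRUCT26)
    voxel_mm3 = float(np.prod(spacing))
    out: list[NoduleCandidate] = []
    for comp_id in range(1, n + 1):
        comp = labels == comp_id
        count = int(comp.sum())
        vol_mm3 = count * voxel_mm3
        diam = (6.0 * vol_mm3 / np.pi) ** (1.0 / 3.0)
        centroid = tuple(float(c) for c in np.argwhere(comp).mean(axis=0))
        circ = {}
        profiles = {}
        for pos in multiview.POSITIONS:
            prof = max_area_slice(comp, pos)
            profiles[pos] = prof
            circ[pos] = circularity(prof)
        n_circular = sum(c >= min_circ for c in circ.values())
        accepted = (diam_range_mm[0] <= diam <= diam_range_mm[1]
                    and n_circular >= 2)
        cand = NoduleCandidate(
            component_id=comp_id,
            voxel_count=count,
            centroid_voxel=centroid,
            centroid_mm=tuple(c * s for c, s in zip(centroid, spacing)),
            equivalent_diameter_mm=float(diam),
            circularity=circ,
            profiles=profiles,
            accepted=accepted,
            mask=comp,
        )
        if accepted or keep_rejected:
            out.append(cand)
    return out


# -- end-to-end segmentation ------------------------------------------

def segment_positions(volume_norm: np.ndarray, nets: dict,
                      prob_threshold: float = 0.5) -> dict[str, np.ndarray]:
    """Per-position 2D inference; returns reassembled 3D binary masks."""
    missing = [p for p in multiview.POSITIONS if p not in nets]
    if missing:
        raise ValueError(f"missing network for position {missing[0]!r}")
    masks = {}
    for pos in multiview.POSITIONS:
        stack = multiview.reslice(volume_norm, pos)
        probs = predict_batched(nets[pos], stack.slices.astype(np.float32))
        masks[pos] = multiview.stack_array(probs >= prob_threshold, pos)
    return masks


def segment_nodules(volume: volio.CTVolume, parenchyma: np.ndarray,
                    nets: dict, cfg: NoduleNetConfig | None = None):
    """Full nodule extraction for one volume.

    The volume is restricted to the parenchyma (everything outside is
    set to air so the networks never see the body wall), resliced into
    the three positions, segmented per position, fused (majority vote by
    default) and screened into candidates. Returns ``(mask, candidates)``
    where ``mask`` is the union of accepted candidates.
    """
    cfg = cfg or NoduleNetConfig()
    parenchyma = np.asarray(parenchyma, bool)
    if parenchyma.shape != volume.shape:
        raise ValueError("parenchyma mask must align with the volume")
    hu = volume.voxels.astype(np.float32)
    hu[~parenchyma] = -1000.0
    norm = volio.normalize_hu(hu)
    pos_masks = segment_positions(norm, nets, cfg.prob_threshold)
    fused = multiview.fuse_position_masks(
        pos_masks["axial"], pos_masks["coronal"], pos_masks["sagittal"],
        rule=cfg.fusion_rule)
    fused &= parenchyma
    candidates = screen_candidates(
        fused, volume.spacing, min_circ=cfg.min_circularity,
        diam_range_mm=cfg.diam_range_mm)
    out_mask = np.zeros_like(fused)
    for cand in candidates:
        out_mask |= cand.mask
    return out_mask, candidates
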