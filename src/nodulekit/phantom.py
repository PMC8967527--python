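"""Synthetic chest-CT phantoms with exact ground truth.

The phantom emulates the structures the pipeline cares about: a
soft-tissue body (an elliptic cylinder at ``body_hu``) containing two
darker axis-aligned ellipsoidal lung fields (``lung_hu``), spherical
nodules of a few mm — smooth or spiculated — rendered at ``nodule_hu``,
axis-aligned cylindrical vessel-like structures, and additive Gaussian
noise. Every structure comes with its exact voxel mask, so segmentation
and sign-recognition stages can be trained and scored without any
external data. Generation is fully determined by the spec's seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .volio import CTVolume, INT16_MAX, INT16_MIN


@dataclass(frozen=True)
class NoduleSpec:
    """One spherical nodule: voxel-coordinate center, physical diameter,
    optional spiculation (radial spikes), and how it attaches to its
    surroundings (isolated in the parenchyma, on the lung wall, or on a
    vessel)."""

    center: tuple[float, float, float]  # (z, y, x) voxels
    diameter_mm: float
    spiculated: bool = False
    spike_count: int = 0
    spike_length_mm: float = 0.0
    attachment: str = "isolated"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")
        if self.spike_count < 0 or self.spike_length_mm < 0:
            raise ValueError("spike parameters must be >= 0")
        if not self.spiculated and self.spike_count != 0:
            raise ValueError("spike_count must be 0 for a smooth nodule")
        if self.spiculated and self.spike_count == 0:
            raise ValueError("a spiculated nodule needs spike_count > 0")
        if self.attachment not in ("isolated", "wall", "vessel"):
            raise ValueError(f"unknown attachment {self.attachment!r}")


@dataclass(frozen=True)
class VesselSpec:
    """A vessel-like tube: an axis-aligned cylinder between two voxel
    coordinates."""

    axis: str  # 'z', 'y' or 'x'
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self):
        if self.axis not in "zyx":
            raise ValueError("axis must be one of z, y, x")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_hu: float = 40.0
    lung_hu: float = -850.0
    nodule_hu: float = 20.0
    vessel_hu: float = 30.0
    noise_sigma: float = 15.0
    nodules: list[NoduleSpec] = field(default_factory=list)
    vessels: list[VesselSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be strictly positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.lung_hu >= self.body_hu:
            raise ValueError("lung_hu must be darker (lower) than body_hu")
        for v in (self.body_hu, self.lung_hu, self.nodule_hu, self.vessel_hu):
            if not (INT16_MIN < v < INT16_MAX):
                raise ValueError("intensity levels must fit signed 16-bit")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# -- geometry helpers --------------------------------------------------

def lung_ellipsoids(shape) -> list[tuple[np.ndarray, np.ndarray]]:
    """(center, semi-axes) in voxels of the two lung fields."""
    z, y, x = shape
    semi = np.array([0.40 * z, 0.30 * y, 0.17 * x])
    left = np.array([z / 2.0, y / 2.0, 0.30 * x])
    right = np.array([z / 2.0, y / 2.0, 0.70 * x])
    return [(left, semi.copy()), (right, semi.copy())]


def _grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=np.float32) for s in shape),
                       indexing="ij", sparse=True)


def _ellipsoid_level(grid, center, semi):
    zz, yy, xx = grid
    return (((zz - center[0]) / semi[0]) ** 2 +
            ((yy - center[1]) / semi[1]) ** 2 +
            ((xx - center[2]) / semi[2]) ** 2)


def lung_mask_for(shape) -> np.ndarray:
    grid = _grid(shape)
    mask = np.zeros(shape, bool)
    for center, semi in lung_ellipsoids(shape):
        mask |= _ellipsoid_level(grid, center, semi) <= 1.0
    return mask


def _body_mask(shape) -> np.ndarray:
    z, y, x = shape
    grid = _grid(shape)
    yy, xx = grid[1], grid[2]
    level = (((yy - y / 2.0) / (0.44 * y)) ** 2 +
             ((xx - x / 2.0) / (0.46 * x)) ** 2)
    return np.broadcast_to(level <= 1.0, shape).copy()


def sphere_mask(shape, center, radius_mm, spacing) -> np.ndarray:
    grid = _grid(shape)
    zz, yy, xx = grid
    d2 = (((zz - center[0]) * spacing[0]) ** 2 +
          ((yy - center[1]) * spacing[1]) ** 2 +
          ((xx - center[2]) * spacing[2]) ** 2)
    return d2 <= radius_mm**2


def cylinder_mask(shape, spec: VesselSpec, spacing) -> np.ndarray:
    axis = "zyx".index(spec.axis)
    grid = _grid(shape)
    start = np.asarray(spec.start, float)
    end = np.asarray(spec.end, float)
    lo, hi = sorted((start[axis], end[axis]))
    other = [i for i in range(3) if i != axis]
    r2 = sum((((grid[i] - start[i]) * spacing[i]) ** 2) for i in other)
    in_radius = r2 <= spec.radius_mm**2
    along = (grid[axis] >= lo) & (grid[axis] <= hi)
    return in_radius & along


# -- spiculation -------------------------------------------------------

def spiculate_boundary(sphere: np.ndarray, spike_count: int,
                       spike_length_mm: float, spacing, seed: int = 0,
                       base_radius_vox: float = 1.5) -> np.ndarray:
    """Add thin radial cone spikes to a sphere mask.

    Spike directions are drawn from the seeded RNG; each spike is a cone
    of ``base_radius_vox`` voxels at the sphere surface tapering to a
    point ``spike_length_mm`` further out. The output is a superset of
    the input, and the spikes lower the circularity of the maximum-area
    axial cross-section — the geometric footprint of the spiculation
    sign.
    """
    sphere = np.asarray(sphere, bool)
    if not sphere.any():
        raise ValueError("sphere_mask is empty")
    if spike_count == 0:
        return sphere.copy()
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing, float)
    idx = np.argwhere(sphere)
    center = idx.mean(axis=0)
    # equivalent radius (mm) from the voxel count
    vol_mm3 = idx.shape[0] * float(np.prod(spacing))
    r_mm = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    out = sphere.copy()
    zz = np.arange(sphere.shape[0])[:, None, None]
    yy = np.arange(sphere.shape[1])[None, :, None]
    xx = np.arange(sphere.shape[2])[None, None, :]
    for _ in range(spike_count):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n_steps = max(2, int(np.ceil(spike_length_mm / min(spacing) * 2)))
        for t in np.linspace(0.0, spike_length_mm, n_steps):
            p = center + d * (r_mm - 0.5 + t) / spacing
            rad = base_radius_vox * (1.0 - 0.8 * t / max(spike_length_mm, 1e-9))
            lo = np.maximum(np.floor(p - rad - 1), 0).astype(int)
            hi = np.minimum(np.ceil(p + rad + 1) + 1,
                            np.asarray(sphere.shape)).astype(int)
            if (hi <= lo).any():
                continue
            sub = (
                (zz[lo[0]:hi[0]] - p[0]) ** 2 +
                (yy[:, lo[1]:hi[1]] - p[1]) ** 2 +
                (xx[:, :, lo[2]:hi[2]] - p[2]) ** 2
            ) <= rad**2
            out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return out


# -- generation --------------------------------------------------------

def generate_phantom(spec: PhantomSpec):
    """Render a phantom volume with exact ground truth.

    Returns ``(volume, parenchyma_mask, nodule_mask, labels)`` where
    ``labels`` is one dict per nodule (index, spiculated flag,
    attachment, center, diameter). Identical specs (including seed)
    produce bit-identical output.
    """
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    lung = lung_mask_for(shape)
    body = _body_mask(shape)

    hu = np.full(shape, -1000.0, dtype=np.float32)
    hu[body] = spec.body_hu
    hu[lung] = spec.lung_hu

    vessel_mask = np.zeros(shape, bool)
    for v in spec.vessels:
        vessel_mask |= cylinder_mask(shape, v, spacing)
    vessel_mask &= lung
    hu[vessel_mask] = spec.vessel_hu

    nodule_mask = np.zeros(shape, bool)
    labels = []
    for i, nod in enumerate(spec.nodules):
        cz, cy, cx = (int(round(c)) for c in nod.center)
        inside = (0 <= cz < shape[0] and 0 <= cy < shape[1] and
                  0 <= cx < shape[2]) and lung[cz, cy, cx]
        if nod.attachment == "wall":
            near = _near_lung_boundary(shape, nod.center)
            if not near:
                raise ValueError(
                    f"nodule {i}: attachment='wall' requires the center on "
                    f"the lung-field boundary (center {nod.center})")
        elif not inside:
            raise ValueError(
                f"nodule {i}: center {nod.center} lies outside the lung fields")
        m = sphere_mask(shape, nod.center, nod.diameter_mm / 2.0, spacing)
        if nod.spiculated:
            m = spiculate_boundary(m, nod.spike_count, nod.spike_length_mm,
                                   spacing, seed=spec.seed * 1000 + i)
        if nod.attachment == "wall":
            m &= body  # the out-of-lung part is chest wall, not nodule
        nodule_mask |= m
        labels.append({
            "index": i,
            "spiculated": nod.spiculated,
            "attachment": nod.attachment,
            "center_voxel": [float(c) for c in nod.center],
            "diameter_mm": nod.diameter_mm,
        })
    hu[nodule_mask] = spec.nodule_hu

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
    hu = np.clip(np.rint(hu), INT16_MIN, INT16_MAX).astype(np.int16)

    parenchyma = lung | nodule_mask
    volume = CTVolume(hu, spacing)
    return volume, parenchyma, nodule_mask, labels


def _near_lung_boundary(shape, center, tol: float = 0.12) -> bool:
    grid = tuple(np.asarray([c], np.float32) for c in center)
    for cen, semi in lung_ellipsoids(shape):
        lvl = float(_ellipsoid_level(grid, cen, semi)[0])
        if abs(lvl - 1.0) <= tol:
            return True
    return False


def sample_nodule_center(shape, rng: np.random.Generator,
                         margin: float = 0.55) -> tuple[float, float, float]:
    """Random position comfortably inside one of the two lung fields."""
    center, semi = lung_ellipsoids(shape)[int(rng.integers(2))]
    while True:
        u = rng.uniform(-margin, margin, size=3)
        if (u**2).sum() <= margin**2:
            p = center + u * semi
            return (float(p[0]), float(p[1]), float(p[2]))


def generate_nodule_set(n_smooth: int, n_spiculated: int, seed: int = 0, *,
                        shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0),
                        diameter_range=(6.0, 8.0), spike_count_range=(6, 10),
                        spike_length_range=(2.0, 4.0), lung_hu: float = -850.0,
                        nodule_hu: float = 20.0, noise_sigma: float = 15.0):
    """A labelled library of single-nodule mini-volumes for sign studies.

    Each sample is a small volume of lung-density background holding one
    centred nodule — smooth or spiculated — with noise, plus its exact
    mask. Returns ``(volumes, masks, labels)`` with ``labels[i] = 1``
    for spiculated. Sizes/spikes are drawn from the seeded RNG, so a
    fixed seed fixes the whole library.
    """
    rng = np.random.default_rng(seed)
    volumes, masks, labels = [], [], []
    flags = [0] * n_smooth + [1] * n_spiculated
    center = tuple(s / 2.0 for s in shape)
    for i, spiculated in enumerate(flags):
        d = rng.uniform(*diameter_range)
        mask = sphere_mask(shape, center, d / 2.0, spacing)
        if spiculated:
            k = int(rng.integers(spike_count_range[0], spike_count_range[1] + 1))
            length = rng.uniform(*spike_length_range)
            mask = spiculate_boundary(mask, k, length, spacing,
                                      seed=int(rng.integers(2**31)))
        hu = np.full(shape, lung_hu, np.float32)
        hu[mask] = nodule_hu
        hu += rng.normal(0.0, noise_sigma, size=shape).astype(np.float32)
        hu = np.clip(np.rint(hu), INT16_MIN, INT16_MAX).astype(np.int16)
        volumes.append(CTVolume(hu, spacing))
        masks.append(mask)
        labels.append(spiculated)
    return volumes, masks, np.asarray(labels, int)


def save_phantom(outdir: str | os.PathLike, volume: CTVolume,
                 parenchyma: np.ndarray, nodule_mask: np.ndarray,
                 labels: list[dict]) -> None:
    """Write volume + masks as NIfTI and the ground truth as JSON."""
    from . import volio

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    volio.write_volume(volume, os.path.join(outdir, "volume.nii.gz"))
    volio.write_mask(parenchyma, volume.spacing,
                     os.path.join(outdir, "parenchyma.nii.gz"))
    volio.write_mask(nodule_mask, volume.spacing,
                     os.path.join(outdir, "nodules.nii.gz"))
    with open(os.path.join(outdir, "labels.json"), "w") as fh:
        json.dump(labels, fh, indent=2)
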