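"""Volume I/O, 16-bit Hounsfield-unit handling and window/level display.

Chest CT stores signed 16-bit intensities on the Hounsfield scale
(air ≈ −1000 HU, water 0 HU, soft tissue ≈ +40 HU). Everything in this
package uses one canonical axis order, (z, y, x) with 0-based indices:
an axial slice is a fixed z, coronal a fixed y, sagittal a fixed x.
Arithmetic is done in floating point; storage stays 16-bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

INT16_MIN, INT16_MAX = np.iinfo(np.int16).min, np.iinfo(np.int16).max

#: Standard lung display window (width/level in HU).
LUNG_WINDOW = None  # set below once WindowSetting exists


@dataclass
class CTVolume:
    """A 3D CT intensity grid in HU with voxel spacing in mm.

    ``voxels`` is int16 indexed (z, y, x); ``spacing`` is mm per axis in
    the same order; ``origin`` is the mm offset of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.voxels.dtype != np.int16:
            if (self.voxels.min() < INT16_MIN or self.voxels.max() > INT16_MAX):
                raise ValueError("intensities exceed the signed 16-bit range")
            self.voxels = np.rint(self.voxels).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class WindowSetting:
    """Display window: ``width`` HU mapped onto gray levels around ``level``."""

    width: float
    level: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be > 0")


LUNG_WINDOW = WindowSetting(width=1500.0, level=-600.0)


# -- NIfTI -------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    # file axes are (x, y, z); our spacing/origin are (z, y, x)
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.voxels.T.astype(np.int16), _affine(volume.spacing, volume.origin))
    nib.save(img, os.fspath(path))


def write_mask(mask: np.ndarray, spacing, path: str | os.PathLike,
               origin=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, np.uint8).T, _affine(spacing, origin))
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a NIfTI file or a DICOM series directory as HU in (z, y, x)."""
    path = os.fspath(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise IOError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path!r} is not a 3D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return CTVolume(data.T, spacing=(zooms[2], zooms[1], zooms[0]),
                    origin=(float(origin[2]), float(origin[1]), float(origin[0])))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    img = nib.load(os.fspath(path))
    return np.asanyarray(img.dataobj).T.astype(bool)


def _read_dicom_series(dirpath: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(dirpath, f) for f in os.listdir(dirpath)
        if not f.startswith("."))
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:  # skip non-DICOM clutter
            continue
    if not datasets:
        raise IOError(f"no readable DICOM files in {dirpath!r}")
    orientations = {tuple(np.round(np.asarray(
        ds.get("ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float), 4))
        for ds in datasets}
    if len(orientations) > 1:
        raise IOError(f"mixed-orientation DICOM series in {dirpath!r}")

    def sort_key(ds):
        pos = ds.get("ImagePositionPatient")
        return float(pos[2]) if pos is not None else int(ds.get("InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    vol = np.stack(slices, axis=0)
    ps = datasets[0].get("PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1 and datasets[0].get("ImagePositionPatient") is not None:
        dz = abs(float(datasets[1].ImagePositionPatient[2]) -
                 float(datasets[0].ImagePositionPatient[2]))
        dz = dz or float(datasets[0].get("SliceThickness", 1.0))
    else:
        dz = float(datasets[0].get("SliceThickness", 1.0))
    return CTVolume(vol, spacing=(dz, float(ps[0]), float(ps[1])))


# -- display -----------------------------------------------------------

def apply_window(volume: CTVolume | np.ndarray,
                 w: WindowSetting = LUNG_WINDOW) -> np.ndarray:
    """Map HU to 8-bit display gray via the window transform.

    display = round(255 · clamp((hu − (level − width/2)) / width, 0, 1)).
    The map is monotone non-decreasing in HU; hu == level lands on the
    midpoint, which rounds (half-to-even) to 128.
    """
    if w.width <= 0:
        raise ValueError("window width must be > 0")
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    lo = w.level - w.width / 2.0
    frac = np.clip((hu.astype(np.float64) - lo) / w.width, 0.0, 1.0)
    return np.rint(frac * 255.0).astype(np.uint8)


def normalize_hu(volume: CTVolume | np.ndarray,
                 w: WindowSetting = LUNG_WINDOW) -> np.ndarray:
    """Windowed intensities scaled to float32 [0, 1] (network input)."""
    hu = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    lo = w.level - w.width / 2.0
    return np.clip((hu.astype(np.float32) - lo) / w.width, 0.0, 1.0)


def export_png(slice_hu: np.ndarray, path: str | os.PathLike,
               w: WindowSetting = LUNG_WINDOW) -> None:
    import imageio.v3 as iio

    iio.imwrite(os.fspath(path), apply_window(slice_hu, w))


# -- resampling --------------------------------------------------------

def resample_isotropic(volume: CTVolume, target_mm: float = 1.0) -> CTVolume:
    """Resample to isotropic voxels with linear interpolation."""
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    factors = tuple(s / target_mm for s in volume.spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return CTVolume(volume.voxels.copy(), (target_mm,) * 3, volume.origin)
    out = ndimage.zoom(volume.voxels.astype(np.float32), factors, order=1)
    out = np.clip(np.rint(out), INT16_MIN, INT16_MAX).astype(np.int16)
    return CTVolume(out, (target_mm,) * 3, volume.origin)


def resample_mask(mask: np.ndarray, spacing, target_mm: float = 1.0) -> np.ndarray:
    """Nearest-neighbour companion of :func:`resample_isotropic` for masks."""
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    factors = tuple(s / target_mm for s in spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return mask.copy()
    return ndimage.zoom(mask.astype(np.uint8), factors, order=0).astype(bool)
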