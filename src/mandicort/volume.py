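"""CBCT volume container, NRRD input/output, and intensity normalization.

Volumes are held as a plain 3D array indexed ``(slice, row, col)`` — axis 0
is the axial (cranio-caudal) direction — together with the per-axis voxel
spacing in millimetres. CBCT acquisitions in this pipeline use isotropic
0.3 mm voxels, which is the fallback spacing when metadata is absent.

Normalization follows the pipeline's fixed contract: a single affine
(min–max) map per volume sending the global minimum to −0.5 and the global
maximum to +0.5. A constant volume, which has no range to stretch, maps to
all zeros.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

DEFAULT_SPACING_MM = (0.3, 0.3, 0.3)
NORM_LO, NORM_HI = -0.5, 0.5


class VolumeFormatError(ValueError):
    """Raised for unreadable or non-3D volume files."""


@dataclass
class CTVolume:
    """A 3D scalar grid with voxel spacing.

    Attributes
    ----------
    data : (n_slices, n_rows, n_cols) float array
    spacing_mm : per-axis voxel size in mm, same axis order as ``data``
    normalized : True once intensities have been mapped to [-0.5, 0.5]
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"volume must be a non-empty 3D grid, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, index: int) -> np.ndarray:
        return self.data[index]


def read_nrrd(path: str | Path) -> CTVolume:
    """Read a 3D NRRD file into a :class:`CTVolume`.

    The array comes back indexed (slice, row, col); spacing is taken from
    the header and reordered to match. The normalized flag is always unset
    on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not read NRRD file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected a 3D volume, got {img.GetDimension()}D data in {path}")
    data = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, col)
    spacing = tuple(reversed(img.GetSpacing()))
    return CTVolume(data=data, spacing_mm=spacing, normalized=False)


def write_nrrd(vol: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    img = sitk.GetImageFromArray(vol.data)
    img.SetSpacing(tuple(reversed(vol.spacing_mm)))
    sitk.WriteImage(img, str(path))
    return path


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_container(vol: CTVolume, path: str | Path) -> Path:
    """Write the volume to the array-container format: NPY + JSON sidecar.

    The sidecar records spacing and the normalized flag so a read-back
    reproduces the volume exactly.
    """
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    try:
        np.save(path, vol.data)
    except OSError as exc:
        raise OSError(f"cannot write container to {path}: {exc}") from exc
    _sidecar(path).write_text(json.dumps(
        {"spacing_mm": list(vol.spacing_mm), "normalized": vol.normalized}))
    return path


def read_container(path: str | Path) -> CTVolume:
    """Read an NPY + sidecar container written by :func:`write_container`.

    A missing sidecar falls back to the acquisition default of 0.3 mm
    isotropic spacing, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such container file: {path}")
    data = np.load(path)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        spacing = tuple(meta["spacing_mm"])
        normalized = bool(meta.get("normalized", False))
    else:
        msg = (f"sidecar {side.name} missing; assuming default spacing "
               f"{DEFAULT_SPACING_MM[0]} mm isotropic")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        spacing, normalized = DEFAULT_SPACING_MM, False
    return CTVolume(data=data, spacing_mm=spacing, normalized=normalized)


def normalize_volume(vol: CTVolume) -> CTVolume:
    """Affine min–max normalization pegging the volume to [-0.5, +0.5].

    Idempotent; a constant volume maps to all zeros.
    """
    if vol.data.size == 0:
        raise ValueError("cannot normalize an empty volume")
    if vol.normalized:
        return replace(vol, data=vol.data.copy())
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi == lo:
        data = np.zeros_like(vol.data)
    else:
        data = (vol.data - lo) / (hi - lo) * (NORM_HI - NORM_LO) + NORM_LO
    return replace(vol, data=data, normalized=True)
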