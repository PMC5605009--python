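"""Volume containers and NIfTI-1 I/O.

Conventions used throughout the package:

* arrays are indexed ``(slice, row, column)``, 0-based;
* ``spacing`` is the per-axis voxel size in mm, in the same order;
* the world coordinate of voxel index ``i`` is ``origin + i * spacing``
  (voxel-centre convention);
* orientation metadata beyond spacing and origin is ignored.

All volumes taking part in a comparison must live on the same grid;
:func:`check_same_grid` is the single gate enforcing that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, VolumeFormatError

__all__ = [
    "ImageVolume",
    "LabelMap",
    "BinaryMask",
    "N_CLASSES",
    "CLASS_NAMES",
    "check_same_grid",
    "read_volume",
    "read_label_map",
    "write_volume",
]

#: anatomy class codes used by every stage of the pipeline
CLASS_NAMES: dict[int, str] = {
    0: "air",
    1: "body",
    2: "eyeball",
    3: "lens",
    4: "cavity",
    5: "ventricle",
    6: "brainstem",
    7: "bone",
}
N_CLASSES = len(CLASS_NAMES)

_SPACING_ATOL_MM = 1e-6
_ORIGIN_ATOL_MM = 1e-3


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """Scalar 3D image: MR intensities (a.u.) or CT numbers (HU)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"ImageVolume requires a 3D array, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("ImageVolume values must be finite")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Per-voxel anatomy class, codes 0..7 (see :data:`CLASS_NAMES`)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise VolumeFormatError(
                f"LabelMap requires a 3D array, got ndim={labels.ndim}"
            )
        as_int = labels.astype(np.int16)
        if not np.array_equal(as_int, labels):
            raise VolumeFormatError("LabelMap requires integer class codes")
        if as_int.min() < 0 or as_int.max() >= N_CLASSES:
            raise VolumeFormatError(
                f"class codes must lie in 0..{N_CLASSES - 1}, "
                f"got range [{as_int.min()}, {as_int.max()}]"
            )
        self.labels = as_int
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Boolean mask on a stated grid (e.g. one anatomy, or the body)."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise VolumeFormatError(
                f"BinaryMask requires a 3D array, got ndim={self.mask.ndim}"
            )
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


def _grid_of(obj) -> tuple[tuple[int, ...], tuple[float, ...], tuple[float, ...]]:
    if isinstance(obj, ImageVolume):
        return obj.values.shape, obj.spacing, obj.origin
    if isinstance(obj, LabelMap):
        return obj.labels.shape, obj.spacing, obj.origin
    if isinstance(obj, BinaryMask):
        return obj.mask.shape, obj.spacing, obj.origin
    raise TypeError(f"unsupported grid object: {type(obj).__name__}")


def check_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` share a grid.

    Shapes must match exactly; spacings within 1e-6 mm; origins within
    1e-3 mm. Returns silently when compatible.
    """
    shape_a, spacing_a, origin_a = _grid_of(a)
    shape_b, spacing_b, origin_b = _grid_of(b)
    if shape_a != shape_b:
        raise GridMismatchError(f"shape mismatch: {shape_a} vs {shape_b}")
    if not np.allclose(spacing_a, spacing_b, rtol=0.0, atol=_SPACING_ATOL_MM):
        raise GridMismatchError(f"spacing mismatch: {spacing_a} vs {spacing_b}")
    if not np.allclose(origin_a, origin_b, rtol=0.0, atol=_ORIGIN_ATOL_MM):
        raise GridMismatchError(f"origin mismatch: {origin_a} vs {origin_b}")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> ImageVolume:
    """Read a scalar 3D NIfTI-1 file into an :class:`ImageVolume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got {data.ndim}D"
        )
    if data.dtype.kind not in "fiub":
        raise VolumeFormatError(f"{path}: non-scalar data of dtype {data.dtype}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ImageVolume(data.astype(np.float64), spacing, origin)


def read_label_map(path) -> LabelMap:
    """Read an integer-typed NIfTI-1 file into a :class:`LabelMap`."""
    vol = read_volume(path)
    labels = np.rint(vol.values)
    if not np.allclose(vol.values, labels, atol=1e-6):
        raise VolumeFormatError(f"{path}: label map contains non-integer values")
    return LabelMap(labels.astype(np.int16), vol.spacing, vol.origin)


def write_volume(vol, path) -> None:
    """Write an :class:`ImageVolume`, :class:`LabelMap` or :class:`BinaryMask`
    to a NIfTI-1 file. Labels and masks are stored integer-typed."""
    path = Path(path)
    if isinstance(vol, ImageVolume):
        data = vol.values.astype(np.float64)
    elif isinstance(vol, LabelMap):
        data = vol.labels.astype(np.int16)
    elif isinstance(vol, BinaryMask):
        data = vol.mask.astype(np.int16)
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
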