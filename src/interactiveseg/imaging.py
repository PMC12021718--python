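"""Geometry-aware volume/mask containers, NIfTI I/O, resampling and
connected-component utilities.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` where ``z`` is the through-slice
  (transverse-stack) axis.  NIfTI files are reoriented to the closest
  canonical (RAS) orientation at load so this convention is unambiguous.
* Voxel coordinates are 0-based; bounding boxes are half-open
  ``[lower, upper)``.
* ``spacing`` is mm per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

AXIS_ORDER = "xyz"


class DimensionalityError(ValueError):
    """Raised when an image is not (reducible to) 3-D."""


@dataclass
class VolumeImage:
    """A 3-D scalar image with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units.
    spacing : tuple of 3 floats
        Voxel size in mm along (x, y, z).
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D array, got {self.voxels.ndim}-D"
            )
        if min(self.voxels.shape) < 1:
            raise DimensionalityError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"axis_order must be {AXIS_ORDER!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """Binary label grid aligned with a :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    grid_id: str | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D mask, got {labels.ndim}-D"
            )
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask labels must be binary (0/1)")
        self.labels = labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def count(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box ``[lower, upper)``."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", tuple(int(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(int(v) for v in self.upper))
        if any(lo >= up for lo, up in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate box {self.lower} .. {self.upper}")
        if any(lo < 0 for lo in self.lower):
            raise ValueError("box extends below the grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(up - lo for lo, up in zip(self.lower, self.upper))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    def contains_point(self, point) -> bool:
        return all(lo <= p < up for p, lo, up in zip(point, self.lower, self.upper))

    def clipped(self, grid_shape) -> "BoundingBox":
        lower = tuple(max(0, lo) for lo in self.lower)
        upper = tuple(min(int(n), up) for up, n in zip(self.upper, grid_shape))
        return BoundingBox(lower, upper)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> VolumeImage:
    """Read a NIfTI volume, reoriented to canonical (RAS) axes.

    4-D images with a trailing singleton axis are squeezed to 3-D; any
    other non-3-D layout raises :class:`DimensionalityError`.
    """
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D image, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: VolumeImage, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float32),
        _affine(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path) -> SegmentationMask:
    vol = read_volume(path)
    labels = (vol.voxels > 0.5).astype(np.uint8)
    return SegmentationMask(labels, vol.spacing, vol.origin)


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(
        mask.labels.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(int)


def resample(volume: VolumeImage, target_spacing, mode: str = "linear") -> VolumeImage:
    """Resample onto ``target_spacing`` (mm).

    Output shape is ``round_half_up(shape * spacing / target)``; voxel
    centers are aligned so output index ``i`` samples input coordinate
    ``i * target / spacing`` (origin-anchored grid).  ``nearest`` mode
    preserves binarity.
    """
    target = np.asarray(target_spacing, dtype=np.float64)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError(f"target_spacing must be 3 positive values, got {target_spacing}")
    src = np.asarray(volume.spacing)
    out_shape = _round_half_up(np.array(volume.shape) * src / target)
    out_shape = np.maximum(out_shape, 1)
    if np.array_equal(out_shape, volume.shape) and np.allclose(target, src):
        return VolumeImage(volume.voxels.copy(), tuple(target), volume.origin)
    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(out_shape, target, src)],
        indexing="ij",
    )
    order = {"linear": 1, "nearest": 0}[mode]
    out = ndimage.map_coordinates(
        np.asarray(volume.voxels, dtype=np.float64),
        np.stack(grids),
        order=order,
        mode="nearest",
    )
    return VolumeImage(out, tuple(target), volume.origin)


def resample_mask(mask: SegmentationMask, target_spacing) -> SegmentationMask:
    vol = VolumeImage(mask.labels.astype(np.float64), mask.spacing, mask.origin)
    out = resample(vol, target_spacing, mode="nearest")
    return SegmentationMask(out.voxels.astype(np.uint8), out.spacing, out.origin)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: SegmentationMask, connectivity: int = 26) -> SegmentationMask:
    """Keep only the largest connected foreground component.

    Empty masks pass through unchanged.  Ties between equal-size
    components are broken by the smallest minimum linear (C-order)
    voxel index, which is independent of the labelling order.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask.labels, structure=_STRUCTS[connectivity])
    if n == 0:
        return SegmentationMask(
            np.zeros_like(mask.labels), mask.spacing, mask.origin, mask.grid_id
        )
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda l: int(np.argmax(flat == l)))
    return SegmentationMask(
        (labels == keep).astype(np.uint8), mask.spacing, mask.origin, mask.grid_id
    )
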