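"""From a reference mask (or a user) to network guidance.

This module covers the interaction half of the pipeline: synthesis of the
six extreme *interior margin points* from a reference segmentation,
user-variability perturbation, extraction of the relaxed volume of
interest (VOI), and the exponentialized geodesic distance (EGD) map that
encodes the clicks for the network.

Interior margin points are one minimum-side and one maximum-side click
per spatial axis, placed just inside the object: extreme foreground
voxels are moved inward along their axis by 5 voxels in-plane, and by
1 voxel along the out-of-plane (max-spacing) axis when the image is
anisotropic (max/min spacing ratio > 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .imaging import BoundingBox, SegmentationMask, VolumeImage

AXIS_SIDES = tuple((axis, side) for axis in range(3) for side in ("min", "max"))


class EmptyObjectError(ValueError):
    """Raised when interactions are requested for an empty mask."""


@dataclass
class InteractionConfig:
    """Constants of the interaction model.

    ``inward_shift_inplane``/``inward_shift_outplane`` are the inward
    displacements (voxels) applied to extreme points; an image counts as
    anisotropic when max(spacing)/min(spacing) > ``anisotropy_threshold``,
    in which case the max-spacing axis uses the out-of-plane shift.
    The VOI around the points is relaxed on each side by
    ``max(relaxation_fraction * extent, relaxation_min_voxels)``.
    """

    inward_shift_inplane: int = 5
    inward_shift_outplane: int = 1
    anisotropy_threshold: float = 3.0
    relaxation_fraction: float = 0.1
    relaxation_min_voxels: int = 5
    perturbation_magnitude: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.inward_shift_inplane < 0 or self.inward_shift_outplane < 0:
            raise ValueError("inward shifts must be >= 0")
        if self.anisotropy_threshold <= 1:
            raise ValueError("anisotropy_threshold must be > 1")
        if self.relaxation_fraction < 0:
            raise ValueError("relaxation_fraction must be >= 0")


@dataclass
class InteriorMarginPoints:
    """Exactly six voxel-coordinate clicks, two per spatial axis."""

    points: np.ndarray  # (6, 3) int
    axis_tags: tuple = AXIS_SIDES

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.shape != (6, 3):
            raise ValueError(f"expected 6 points of 3 coordinates, got {pts.shape}")
        self.points = pts

    def validate(self, grid_shape, mask: SegmentationMask | None = None) -> None:
        """Check all points are inside the grid (and on foreground, if a mask is given)."""
        if np.any(self.points < 0) or np.any(self.points >= np.asarray(grid_shape)):
            raise ValueError("point outside the image grid")
        if mask is not None:
            for p in self.points:
                if not mask.labels[tuple(p)]:
                    raise ValueError(f"point {tuple(p)} not on foreground")

    def shifted(self, offset) -> "InteriorMarginPoints":
        return InteriorMarginPoints(self.points - np.asarray(offset, dtype=int), self.axis_tags)


@dataclass
class GeodesicMap:
    """EGD values on the VOI grid; 1 exactly at the seed voxels, in (0, 1] everywhere."""

    values: np.ndarray
    seed_indices: np.ndarray


def out_of_plane_axis(spacing, threshold: float = 3.0) -> int | None:
    """The max-spacing axis if the grid is anisotropic, else None."""
    sp = np.asarray(spacing, dtype=float)
    if sp.max() / sp.min() > threshold:
        return int(np.argmax(sp))
    return None


def _extreme_voxel(fg: np.ndarray, axis: int, side: str) -> np.ndarray:
    """Deterministic representative of the extreme face along ``axis``.

    Among foreground voxels achieving the extreme coordinate, the one
    closest to the centroid of that face is chosen; remaining ties go to
    the smallest linear index.
    """
    coords = fg[:, axis]
    extreme = coords.min() if side == "min" else coords.max()
    face = fg[coords == extreme]
    centroid = face.mean(axis=0)
    d2 = ((face - centroid) ** 2).sum(axis=1)
    # face rows are in C-order scan order, so argmin ties resolve to the
    # smallest linear index automatically
    return face[int(np.argmin(d2))].copy()


def simulate_points(
    mask: SegmentationMask, spacing=None, cfg: InteractionConfig | None = None
) -> InteriorMarginPoints:
    """Synthesize the six interior margin points from a reference mask.

    For each axis and side the extreme foreground voxel is shifted
    inward along that axis by the configured amount (5 voxels in-plane;
    1 voxel along the out-of-plane axis of anisotropic grids).  If the
    shifted location leaves the object the shift is reduced stepwise
    until the point is foreground again, so all returned points lie
    inside the object.
    """
    cfg = cfg or InteractionConfig()
    spacing = mask.spacing if spacing is None else spacing
    fg = np.argwhere(mask.labels > 0)
    if len(fg) == 0:
        raise EmptyObjectError("cannot place interior margin points on an empty mask")
    oop = out_of_plane_axis(spacing, cfg.anisotropy_threshold)
    labels = mask.labels
    points = []
    for axis, side in AXIS_SIDES:
        p = _extreme_voxel(fg, axis, side)
        shift = cfg.inward_shift_outplane if axis == oop else cfg.inward_shift_inplane
        direction = 1 if side == "min" else -1
        while shift > 0:
            q = p.copy()
            q[axis] += direction * shift
            if 0 <= q[axis] < labels.shape[axis] and labels[tuple(q)]:
                p = q
                break
            shift -= 1
        points.append(p)
    pts = InteriorMarginPoints(np.array(points))
    pts.validate(mask.shape, mask)
    return pts


def perturb_points(
    pts: InteriorMarginPoints, mask: SegmentationMask, cfg: InteractionConfig
) -> InteriorMarginPoints:
    """Simulate user variability: jitter each coordinate by a uniform
    integer offset in [-magnitude, +magnitude].

    Offsets landing on background are re-drawn (up to 50 tries), then
    clamped to the nearest foreground voxel, so the output stays a valid
    set of interior points.  Fully deterministic given ``cfg.rng_seed``.
    """
    mag = int(cfg.perturbation_magnitude)
    if mag == 0:
        return InteriorMarginPoints(pts.points.copy(), pts.axis_tags)
    rng = np.random.default_rng(cfg.rng_seed)
    labels = mask.labels
    shape = np.asarray(mask.shape)
    fg = np.argwhere(labels > 0)
    out = []
    for p in pts.points:
        chosen = None
        for _ in range(50):
            q = p + rng.integers(-mag, mag + 1, size=3)
            if np.all(q >= 0) and np.all(q < shape) and labels[tuple(q)]:
                chosen = q
                break
        if chosen is None:
            q = p + rng.integers(-mag, mag + 1, size=3)
            d2 = ((fg - q) ** 2).sum(axis=1)
            chosen = fg[int(np.argmin(d2))]
        out.append(chosen)
    result = InteriorMarginPoints(np.array(out), pts.axis_tags)
    result.validate(mask.shape, mask)
    return result


def compute_voi(
    pts: InteriorMarginPoints, grid_shape, cfg: InteractionConfig | None = None
) -> BoundingBox:
    """Relaxed VOI around the six points.

    The tight point box is expanded on each side along axis ``a`` by
    ``max(relaxation_fraction * extent_a, relaxation_min_voxels)`` and
    clipped to the grid; the relaxation exists to guarantee the box
    encapsulates the whole object, not just the clicked points.
    """
    cfg = cfg or InteractionConfig()
    pts.validate(grid_shape)
    lo = pts.points.min(axis=0)
    hi = pts.points.max(axis=0)
    extent = hi - lo
    relax = np.maximum(
        np.floor(cfg.relaxation_fraction * extent + 0.5).astype(int),
        cfg.relaxation_min_voxels,
    )
    lower = np.maximum(lo - relax, 0)
    upper = np.minimum(hi + relax + 1, np.asarray(grid_shape, dtype=int))
    return BoundingBox(tuple(lower), tuple(upper))


def _edge_arrays(image: np.ndarray, spacing, lam: float):
    """Weights of the 6-connected voxel graph, one axis at a time."""
    shape = image.shape
    n = image.size
    idx = np.arange(n).reshape(shape)
    rows, cols, weights = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        di = image[tuple(sl_b)].ravel() - image[tuple(sl_a)].ravel()
        w = np.sqrt((1.0 - lam) * float(spacing[axis]) ** 2 + lam * di * di)
        rows.append(a)
        cols.append(b)
        weights.append(w)
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(weights),
        n,
    )


def egd_map(
    image_crop: VolumeImage,
    pts_in_crop: InteriorMarginPoints,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> GeodesicMap:
    """Exponentialized geodesic distance map of the six clicks.

    For every voxel the geodesic distance D to the nearest seed is the
    shortest-path cost on the 6-connected voxel graph with edge weight

        w(u, v) = sqrt((1 - lam) * d_mm(u, v)^2 + lam * (I(u) - I(v))^2)

    and the map value is exp(-alpha * D): exactly 1 at the seeds,
    decaying with combined spatial and intensity distance, so voxels
    similar and close to the clicks are highlighted.  ``lam`` trades
    intensity against spatial cost (1 = pure intensity); the image is
    expected to be intensity-normalized already so ``alpha`` is
    scale-free.
    """
    img = np.asarray(image_crop.voxels, dtype=np.float64)
    pts_in_crop.validate(img.shape)
    rows, cols, weights, n = _edge_arrays(img, image_crop.spacing, lam)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    seeds = np.ravel_multi_index(pts_in_crop.points.T, img.shape)
    dist = dijkstra(graph, directed=False, indices=np.unique(seeds), min_only=True)
    values = np.exp(-alpha * dist.reshape(img.shape))
    return GeodesicMap(values=values, seed_indices=pts_in_crop.points.copy())


# ---------------------------------------------------------------------------
# Points JSON interchange: {"space": "voxel", "points": [[x,y,z] x 6], ...}

def save_points(pts: InteriorMarginPoints, path, image: str | None = None) -> None:
    payload = {"space": "voxel", "points": pts.points.tolist()}
    if image is not None:
        payload["image"] = str(image)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_points(path, grid_shape=None) -> InteriorMarginPoints:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("space", "voxel") != "voxel":
        raise ValueError("points file must use voxel space")
    pts = InteriorMarginPoints(np.asarray(payload["points"], dtype=int))
    if grid_shape is not None:
        pts.validate(grid_shape)
    return pts
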