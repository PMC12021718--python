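"""Synthetic CT/MRI-like phantoms with a single blob-shaped lesion.

Each phantom is a smooth textured background plus one lobulated
ellipsoidal lesion (the ground truth) and, optionally, decoy blobs of
the same intensity that are *not* part of the mask.  The knobs mirror
the failure modes of real soft-tissue tumor imaging: ``contrast``
(lesion-background separation in noise-SD units), ``noise_sd``,
``lobulation`` (smooth radial boundary deformation, emulating irregular
tumor margins), and anisotropic spacing (thick-slice acquisitions).
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import SegmentationMask, VolumeImage, write_mask, write_volume
from .interactions import InteractionConfig, save_points, simulate_points


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_semiaxes_range: tuple[float, float] = (8.0, 14.0)  # mm
    lobulation: float = 0.2  # fractional radial deformation amplitude
    contrast: float = 4.0  # lesion offset in noise-SD units
    noise_sd: float = 1.0
    background_texture: float = 0.5  # smooth random-field amplitude (noise-SD units)
    soft_edge: bool = True  # 1-voxel partial-volume ramp at the boundary
    n_decoys: int = 0
    decoy_min_separation: float = 3.0  # voxels between lesion and decoy surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < d for s, d in zip(self.shape, (24, 24, 8))):
            raise ValueError(f"shape {self.shape} below the (24, 24, 8) minimum")
        if self.lobulation < 0 or self.noise_sd < 0:
            raise ValueError("lobulation and noise_sd must be >= 0")


class LesionFitError(ValueError):
    """Raised when the requested lesion cannot fit inside the grid."""


def _smooth_sphere_function(rng: np.random.Generator, order: int = 4):
    """A smooth random function on the unit sphere with max|f| ~ 1,
    built from a few random quadratic-direction lobes (a low-order
    spherical-harmonic-like perturbation)."""
    dirs = rng.normal(size=(order, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    amps = rng.uniform(-1.0, 1.0, size=order)

    def f(u: np.ndarray) -> np.ndarray:
        # u: (..., 3) unit vectors
        proj = u @ dirs.T  # (..., order)
        vals = (proj**2 * amps).sum(axis=-1)
        return vals

    # normalize to unit max magnitude on a sample of directions
    probe = rng.normal(size=(512, 3))
    probe /= np.linalg.norm(probe, axis=1, keepdims=True)
    scale = np.abs(f(probe)).max()
    return (lambda u: f(u) / scale) if scale > 0 else f


def _lesion_fields(shape, spacing, center_mm, semiaxes_mm, lob_fn, lobulation):
    """Continuous signed boundary offset (in voxel units) of a lobulated
    ellipsoid; positive inside."""
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    rel = np.stack(grids, axis=-1) - np.asarray(center_mm)  # (..., 3) mm
    dist = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dist[..., None] > 0, rel / dist[..., None], 0.0)
    rho = np.sqrt(((rel / np.asarray(semiaxes_mm)) ** 2).sum(axis=-1))
    bound = 1.0 + (lobulation * lob_fn(u) if lobulation > 0 else 0.0)
    # convert the dimensionless (bound - rho) to ~voxels from the boundary
    mean_semi = float(np.mean(semiaxes_mm))
    mean_spacing = float(np.mean(spacing))
    return (bound - rho) * mean_semi / mean_spacing


def generate_phantom(cfg: PhantomConfig, return_decoy_mask: bool = False):
    """One phantom volume and its ground-truth lesion mask.

    The lesion is an ellipsoid with random center and semi-axes whose
    radius is perturbed by a smooth low-order angular deformation of
    amplitude ``lobulation``; decoys share the lesion intensity but are
    excluded from the mask.  With ``return_decoy_mask`` the union of the
    decoy blobs is returned as a third mask (used by blob-designation
    experiments).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape)
    spacing = np.asarray(cfg.spacing, dtype=float)
    extent_mm = shape * spacing
    unit = cfg.noise_sd if cfg.noise_sd > 0 else 1.0

    lo, hi = cfg.lesion_semiaxes_range
    semiaxes = rng.uniform(lo, hi, size=3)
    # cap the semi-axes so the lobulated lesion plus a 2-voxel margin fits
    # even on small or thick-slice (anisotropic) grids
    max_semi = (extent_mm / 2.0 - 2.0 * spacing) / (1.0 + cfg.lobulation)
    semiaxes = np.minimum(semiaxes, max_semi)
    if np.any(semiaxes <= spacing):
        raise LesionFitError(
            f"lesion semi-axes {semiaxes} cannot fit grid extent {extent_mm} mm"
        )
    margin = semiaxes * (1 + cfg.lobulation) + 2.0 * spacing
    lo_c, hi_c = margin, extent_mm - margin
    center = rng.uniform(lo_c, np.maximum(hi_c, lo_c))

    lob_fn = _smooth_sphere_function(rng)
    d = _lesion_fields(cfg.shape, spacing, center, semiaxes, lob_fn, cfg.lobulation)
    mask = (d >= 0).astype(np.uint8)
    soft = np.clip(d + 0.5, 0.0, 1.0) if cfg.soft_edge else mask.astype(np.float64)

    image = np.zeros(cfg.shape, dtype=np.float64)
    if cfg.background_texture > 0:
        field_ = rng.normal(size=cfg.shape)
        field_ = ndimage.gaussian_filter(field_, sigma=6.0)
        sd = field_.std()
        if sd > 0:
            image += cfg.background_texture * unit * field_ / sd

    lesion_signal = cfg.contrast * unit
    image += lesion_signal * soft

    # decoys: same intensity, disjoint from the lesion
    decoy_mask = np.zeros(cfg.shape, dtype=np.uint8)
    placed = 0
    attempts = 0
    while placed < cfg.n_decoys and attempts < 200:
        attempts += 1
        dsemi = rng.uniform(lo, hi, size=3)
        dsemi = np.minimum(dsemi, max_semi)
        dmargin = dsemi * (1 + cfg.lobulation) + 2.0 * spacing
        if np.any(dmargin >= extent_mm - dmargin):
            continue
        dcenter = rng.uniform(dmargin, extent_mm - dmargin)
        sep = np.linalg.norm(dcenter - center)
        need = (
            semiaxes.max() * (1 + cfg.lobulation)
            + dsemi.max() * (1 + cfg.lobulation)
            + cfg.decoy_min_separation * float(spacing.min())
        )
        if sep < need:
            continue
        dd = _lesion_fields(cfg.shape, spacing, dcenter, dsemi, lob_fn, cfg.lobulation)
        dsoft = np.clip(dd + 0.5, 0.0, 1.0) if cfg.soft_edge else (dd >= 0).astype(float)
        image += lesion_signal * dsoft
        decoy_mask |= (dd >= 0).astype(np.uint8)
        placed += 1
    if placed < cfg.n_decoys:
        raise LesionFitError("could not place the requested decoy blobs")

    if cfg.noise_sd > 0:
        image += rng.normal(scale=cfg.noise_sd, size=cfg.shape)

    vol = VolumeImage(image, tuple(spacing))
    out_mask = SegmentationMask(mask, tuple(spacing))
    if return_decoy_mask:
        return vol, out_mask, SegmentationMask(decoy_mask, tuple(spacing))
    return vol, out_mask


def generate_cohort(
    n: int,
    cfg: PhantomConfig,
    out_dir,
    interaction: InteractionConfig | None = None,
) -> Path:
    """Write an n-case dataset in the pipeline layout:
    ``images/*.nii.gz``, ``masks/*.nii.gz``, ``points/*.json`` matched by
    stem, plus a ``manifest.csv`` of per-case seeds and parameters.

    Per-case seeds are derived deterministically from ``cfg.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    interaction = interaction or InteractionConfig()
    out = Path(out_dir)
    for sub in ("images", "masks", "points"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for k in range(n):
        case_seed = int(np.random.SeedSequence([cfg.seed, k]).generate_state(1)[0] % 2**31)
        case_cfg = replace(cfg, seed=case_seed)
        vol, mask = generate_phantom(case_cfg)
        pts = simulate_points(mask, cfg=interaction)
        stem = f"case_{k:03d}"
        write_volume(vol, out / "images" / f"{stem}.nii.gz")
        write_mask(mask, out / "masks" / f"{stem}.nii.gz")
        save_points(pts, out / "points" / f"{stem}.json", image=f"images/{stem}.nii.gz")
        rows.append(
            {
                "case_id": stem,
                "seed": case_seed,
                "contrast": cfg.contrast,
                "noise_sd": cfg.noise_sd,
                "lobulation": cfg.lobulation,
                "n_decoys": cfg.n_decoys,
                "spacing": "x".join(str(s) for s in cfg.spacing),
                "mask_voxels": mask.count(),
            }
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out


def load_cohort(data_dir):
    """Yield (case_id, VolumeImage, SegmentationMask, InteriorMarginPoints)
    triples from a dataset directory in the pipeline layout."""
    from .imaging import read_mask, read_volume
    from .interactions import load_points

    data = Path(data_dir)
    for img_path in sorted((data / "images").glob("*.nii*")):
        stem = img_path.name.replace(".nii.gz", "").replace(".nii", "")
        vol = read_volume(img_path)
        mask = read_mask(data / "masks" / img_path.name)
        pts = load_points(data / "points" / f"{stem}.json", grid_shape=vol.shape)
        yield stem, vol, mask, pts
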