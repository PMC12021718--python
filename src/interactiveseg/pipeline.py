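"""The learning half of the interactive segmentation method.

Given an image and six interior margin points, the pipeline crops the
relaxed VOI, optionally resamples it to a target spacing, normalizes
intensities, computes the EGD guidance channel, pads to the network
input shape, runs the (ensembled) encoder-decoder, and restores the
prediction to the original image grid with optional largest-component
postprocessing.  Geometry provenance is carried explicitly so the
inverse mapping is exact whenever no resampling was applied.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .imaging import BoundingBox, SegmentationMask, VolumeImage, largest_component
from .interactions import (
    InteractionConfig,
    InteriorMarginPoints,
    compute_voi,
    egd_map,
)
from .network import Adam, ConfigurationError, UNet3D, dice_ce_loss, softmax


@dataclass
class NetworkConfig:
    depth: int = 3
    base_channels: int = 8
    norm: str = "instance"
    nonlinearity: str = "leaky_relu"


@dataclass
class TrainingConfig:
    epochs: int = 8
    batch_size: int = 1
    learning_rate: float = 1e-2
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (dice, cross-entropy)
    folds: int = 1
    seed: int = 0


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; the "tiny" defaults train on a
    desk CPU in minutes."""

    target_spacing: tuple[float, float, float] | None = None  # None = native
    normalization: str = "mri"  # {ct|mri}
    crop_pad_shape: tuple[int, int, int] = (32, 32, 32)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    postprocess_largest_component: bool = True
    interaction: InteractionConfig = field(default_factory=InteractionConfig)
    egd_alpha: float = 1.0
    egd_lam: float = 1.0
    use_egd_channel: bool = True  # False = image-only ablation

    def __post_init__(self) -> None:
        if self.training.folds < 1:
            raise ConfigurationError("folds must be >= 1")
        div = 2**self.network.depth
        if any(s % div for s in self.crop_pad_shape):
            raise ConfigurationError(
                f"crop_pad_shape {self.crop_pad_shape} must be divisible by {div}"
            )
        if self.normalization not in ("ct", "mri"):
            raise ConfigurationError("normalization must be 'ct' or 'mri'")


@dataclass
class DatasetStats:
    """Foreground intensity statistics of a CT training cohort."""

    clip_lower: float
    clip_upper: float
    mean: float
    sd: float


@dataclass
class Provenance:
    """Geometry record sufficient to restore a VOI-grid prediction to the
    original image grid."""

    original_shape: tuple[int, int, int]
    original_spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    box: BoundingBox
    target_spacing: tuple[float, float, float]
    resampled_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int]


@dataclass
class ModelInput:
    channels: np.ndarray  # (2, X, Y, Z) on the padded VOI grid
    points: InteriorMarginPoints  # in padded-grid coordinates
    provenance: Provenance


@dataclass
class Ensemble:
    members: list[UNet3D]
    config: PipelineConfig
    fold_assignments: list[list[int]]
    ct_stats: DatasetStats | None = None


# ---------------------------------------------------------------------------
# preprocessing


def compute_ct_stats(
    volumes: list[VolumeImage], masks: list[SegmentationMask]
) -> DatasetStats:
    """Cohort foreground statistics for CT normalization: clip range at
    the 0.5/99.5 percentiles, then the mean/sd of the clipped values."""
    fg = np.concatenate(
        [v.voxels[m.labels > 0].ravel() for v, m in zip(volumes, masks)]
    )
    lo, hi = np.percentile(fg, [0.5, 99.5])
    clipped = np.clip(fg, lo, hi)
    sd = float(clipped.std())
    return DatasetStats(float(lo), float(hi), float(clipped.mean()), sd if sd > 0 else 1.0)


def normalize(
    volume: VolumeImage, mode: str = "mri", stats: DatasetStats | None = None
) -> VolumeImage:
    """Intensity normalization following common self-configuring practice.

    ``ct``: clip to the dataset foreground [p0.5, p99.5] window then
    standardize with the dataset mean/sd (requires ``stats``).
    ``mri``: per-volume z-score over the nonzero region.  Constant
    volumes map to all-zeros.
    """
    x = np.asarray(volume.voxels, dtype=np.float64)
    if mode == "ct":
        if stats is None:
            raise ConfigurationError("ct normalization requires dataset stats")
        out = (np.clip(x, stats.clip_lower, stats.clip_upper) - stats.mean) / stats.sd
    elif mode == "mri":
        region = x != 0
        if not region.any():
            region = np.ones_like(x, dtype=bool)
        mu = x[region].mean()
        sd = x[region].std()
        out = np.zeros_like(x) if sd == 0 else (x - mu) / sd
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    return VolumeImage(out, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# geometry: crop -> resample -> pad, and its inverse


def _resize_nearest(arr: np.ndarray, out_shape, scale) -> np.ndarray:
    """Nearest-neighbor resize where output index i samples input
    coordinate i * scale (origin-anchored, same convention as resample)."""
    from scipy import ndimage

    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(out_shape, scale)], indexing="ij"
    )
    return ndimage.map_coordinates(arr, np.stack(coords), order=0, mode="nearest")


def _resize_linear(arr: np.ndarray, out_shape, scale) -> np.ndarray:
    from scipy import ndimage

    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(out_shape, scale)], indexing="ij"
    )
    return ndimage.map_coordinates(
        arr.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )


def _plan_geometry(
    image_shape, spacing, pts: InteriorMarginPoints, cfg: PipelineConfig
) -> Provenance:
    """Compute the VOI box (expanded toward the network input shape so
    padding carries real image context where available) and the
    resampling/padding record."""
    voi = compute_voi(pts, image_shape, cfg.interaction)
    target = tuple(cfg.target_spacing) if cfg.target_spacing else tuple(spacing)
    scale = np.asarray(target) / np.asarray(spacing)  # native voxels per target voxel
    want_native = np.ceil(np.asarray(cfg.crop_pad_shape) * scale).astype(int)
    lower = np.asarray(voi.lower)
    upper = np.asarray(voi.upper)
    grow = np.maximum(want_native - (upper - lower), 0)
    lower = lower - grow // 2
    upper = upper + (grow - grow // 2)
    shift = np.maximum(-lower, 0)
    lower += shift
    upper += shift
    shift = np.maximum(upper - np.asarray(image_shape), 0)
    upper -= shift
    lower = np.maximum(lower - shift, 0)
    box = BoundingBox(tuple(lower), tuple(upper))
    native_shape = np.asarray(box.shape)
    resampled_shape = np.maximum(
        np.floor(native_shape / scale + 0.5).astype(int), 1
    )
    pad_before = (np.asarray(cfg.crop_pad_shape) - resampled_shape) // 2
    return Provenance(
        original_shape=tuple(int(s) for s in image_shape),
        original_spacing=tuple(float(s) for s in spacing),
        origin=(0.0, 0.0, 0.0),
        box=box,
        target_spacing=target,
        resampled_shape=tuple(int(s) for s in resampled_shape),
        pad_before=tuple(int(p) for p in pad_before),
    )


def _place(arr: np.ndarray, out_shape, pad_before) -> np.ndarray:
    """Center-place ``arr`` into a zero canvas of ``out_shape``; negative
    offsets crop instead of pad."""
    out = np.zeros(tuple(out_shape), dtype=arr.dtype)
    src_lo, dst_lo, length = [], [], []
    for s, o, p in zip(arr.shape, out_shape, pad_before):
        sl = max(0, -p)
        dl = max(0, p)
        ln = min(s - sl, o - dl)
        src_lo.append(sl)
        dst_lo.append(dl)
        length.append(max(ln, 0))
    if min(length) > 0:
        out[
            dst_lo[0] : dst_lo[0] + length[0],
            dst_lo[1] : dst_lo[1] + length[1],
            dst_lo[2] : dst_lo[2] + length[2],
        ] = arr[
            src_lo[0] : src_lo[0] + length[0],
            src_lo[1] : src_lo[1] + length[1],
            src_lo[2] : src_lo[2] + length[2],
        ]
    return out


def _forward_geometry(
    arr: np.ndarray, prov: Provenance, pad_shape, nearest: bool
) -> np.ndarray:
    crop = arr[prov.box.slices()]
    scale = np.asarray(prov.target_spacing) / np.asarray(prov.original_spacing)
    if not np.allclose(scale, 1.0):
        fn = _resize_nearest if nearest else _resize_linear
        crop = fn(crop, prov.resampled_shape, scale)
    return _place(crop, pad_shape, prov.pad_before)


def restore_to_original_grid(pred: np.ndarray, prov: Provenance) -> np.ndarray:
    """Inverse of the crop/resample/pad geometry (nearest-neighbor for
    labels); voxels outside the VOI are 0.  Exact when target spacing
    equals native spacing."""
    rs = _place(pred, prov.resampled_shape, tuple(-p for p in prov.pad_before))
    scale = np.asarray(prov.target_spacing) / np.asarray(prov.original_spacing)
    if not np.allclose(scale, 1.0):
        rs = _resize_nearest(rs, prov.box.shape, 1.0 / scale)
    out = np.zeros(prov.original_shape, dtype=pred.dtype)
    out[prov.box.slices()] = rs
    return out


def _points_in_pad_grid(
    pts: InteriorMarginPoints, prov: Provenance, pad_shape
) -> InteriorMarginPoints:
    scale = np.asarray(prov.target_spacing) / np.asarray(prov.original_spacing)
    p = (pts.points - np.asarray(prov.box.lower)) / scale
    p = np.floor(p + 0.5).astype(int) + np.asarray(prov.pad_before)
    p = np.clip(p, 0, np.asarray(pad_shape) - 1)
    return InteriorMarginPoints(p, pts.axis_tags)


def make_model_input(
    image: VolumeImage,
    pts: InteriorMarginPoints,
    cfg: PipelineConfig,
    ct_stats: DatasetStats | None = None,
) -> ModelInput:
    """Compose VOI crop -> resample -> normalize -> EGD -> pad into the
    2-channel network input."""
    pts.validate(image.shape)
    prov = _plan_geometry(image.shape, image.spacing, pts, cfg)
    prov = replace(prov, origin=image.origin)
    img_chan = _forward_geometry(
        np.asarray(image.voxels, dtype=np.float64), prov, cfg.crop_pad_shape, nearest=False
    )
    norm = normalize(
        VolumeImage(img_chan, prov.target_spacing), cfg.normalization, ct_stats
    )
    pts_pad = _points_in_pad_grid(pts, prov, cfg.crop_pad_shape)
    egd = egd_map(norm, pts_pad, alpha=cfg.egd_alpha, lam=cfg.egd_lam)
    channels = np.stack([norm.voxels, egd.values]).astype(np.float32)
    return ModelInput(channels=channels, points=pts_pad, provenance=prov)


def mask_to_model_grid(mask: SegmentationMask, prov: Provenance, pad_shape) -> np.ndarray:
    """Push a reference mask through the same geometry (nearest)."""
    return _forward_geometry(mask.labels, prov, pad_shape, nearest=True)


# ---------------------------------------------------------------------------
# network construction / training / inference


def build_network(cfg: PipelineConfig, seed: int | None = None) -> UNet3D:
    """Untrained network per the configuration; identical config + seed
    gives bit-identical initial parameters."""
    net = UNet3D(
        depth=cfg.network.depth,
        base_channels=cfg.network.base_channels,
        in_channels=2 if cfg.use_egd_channel else 1,
        out_channels=2,
        norm=cfg.network.norm,
        nonlinearity=cfg.network.nonlinearity,
        seed=cfg.training.seed if seed is None else seed,
    )
    net.check_input_shape(cfg.crop_pad_shape)
    return net


def _net_channels(mi: ModelInput, cfg: PipelineConfig) -> np.ndarray:
    return mi.channels if cfg.use_egd_channel else mi.channels[:1]


def _dsc(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    tot = a.sum() + b.sum()
    return 1.0 if tot == 0 else 2.0 * inter / tot


def train(
    cases: list[tuple[VolumeImage, SegmentationMask, InteriorMarginPoints]],
    cfg: PipelineConfig,
    log_path=None,
    ct_stats: DatasetStats | None = None,
) -> Ensemble:
    """K-fold cross-validation training of the ensemble.

    Each fold's member minimizes soft Dice + cross-entropy on
    (model input -> mask-in-VOI) pairs with Adam; ``folds=1`` trains a
    single member on all cases (validated on the training cases).  Fully
    seeded: case shuffling, fold splits and initialization all derive
    from ``cfg.training.seed``.
    """
    tr = cfg.training
    if len(cases) < tr.folds:
        raise ConfigurationError(
            f"{len(cases)} cases cannot fill {tr.folds} folds"
        )
    if cfg.normalization == "ct" and ct_stats is None:
        ct_stats = compute_ct_stats([c[0] for c in cases], [c[1] for c in cases])

    prepared = []
    for img, mask, pts in cases:
        mi = make_model_input(img, pts, cfg, ct_stats)
        target = mask_to_model_grid(mask, mi.provenance, cfg.crop_pad_shape)
        prepared.append((_net_channels(mi, cfg), target))

    rng = np.random.default_rng(tr.seed)
    order = rng.permutation(len(cases))
    if tr.folds == 1:
        folds = [(list(order), list(order))]
    else:
        chunks = np.array_split(order, tr.folds)
        folds = [
            (
                [i for j, ch in enumerate(chunks) if j != k for i in ch],
                list(chunks[k]),
            )
            for k in range(tr.folds)
        ]

    log_rows = []
    members = []
    assignments = []
    for k, (train_idx, val_idx) in enumerate(folds):
        net = build_network(cfg, seed=tr.seed + 1000 * (k + 1))
        opt = Adam(net.params, lr=tr.learning_rate)
        fold_rng = np.random.default_rng(tr.seed + 7919 * (k + 1))
        for epoch in range(tr.epochs):
            epoch_loss = 0.0
            for i in fold_rng.permutation(train_idx):
                x, t = prepared[i]
                logits, cache = net.forward(x, want_cache=True)
                loss, _, _, dlog = dice_ce_loss(
                    logits, t, weights=tr.loss_weights
                )
                grads = net.backward(dlog, cache)
                opt.step(net.params, grads)
                epoch_loss += loss
            val_dsc = float(
                np.mean(
                    [
                        _dsc(
                            np.argmax(net.forward(prepared[i][0]), axis=0),
                            prepared[i][1],
                        )
                        for i in val_idx
                    ]
                )
            )
            log_rows.append(
                {
                    "fold": k,
                    "epoch": epoch,
                    "loss": epoch_loss / max(len(train_idx), 1),
                    "val_dsc": val_dsc,
                }
            )
        members.append(net)
        assignments.append([int(i) for i in val_idx])

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["fold", "epoch", "loss", "val_dsc"])
            writer.writeheader()
            writer.writerows(log_rows)
    ens = Ensemble(members=members, config=cfg, fold_assignments=assignments, ct_stats=ct_stats)
    ens.training_log = log_rows
    return ens


def predict(
    image: VolumeImage, pts: InteriorMarginPoints, ens: Ensemble
) -> SegmentationMask:
    """Ensembled prediction restored to the original image grid.

    Member softmax maps are averaged, argmaxed to a binary mask,
    optionally reduced to the largest connected component, and mapped
    back through the inverse VOI geometry (nearest-neighbor); everything
    outside the VOI is background.
    """
    cfg = ens.config
    mi = make_model_input(image, pts, cfg, ens.ct_stats)
    x = _net_channels(mi, cfg)
    proba = np.mean([softmax(m.forward(x)) for m in ens.members], axis=0)
    label = (np.argmax(proba, axis=0) == 1).astype(np.uint8)
    full = restore_to_original_grid(label, mi.provenance)
    out = SegmentationMask(full, image.spacing, image.origin)
    if cfg.postprocess_largest_component and out.count() > 0:
        out = largest_component(out, connectivity=26)
    return out


# ---------------------------------------------------------------------------
# config + ensemble persistence


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["training"]["loss_weights"] = list(cfg.training.loss_weights)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "network" in d and isinstance(d["network"], dict):
        d["network"] = NetworkConfig(**d["network"])
    if "training" in d and isinstance(d["training"], dict):
        t = dict(d["training"])
        if "loss_weights" in t:
            t["loss_weights"] = tuple(t["loss_weights"])
        d["training"] = TrainingConfig(**t)
    if "interaction" in d and isinstance(d["interaction"], dict):
        d["interaction"] = InteractionConfig(**d["interaction"])
    if d.get("target_spacing") is not None:
        d["target_spacing"] = tuple(d["target_spacing"])
    if "crop_pad_shape" in d:
        d["crop_pad_shape"] = tuple(d["crop_pad_shape"])
    return PipelineConfig(**d)


def save_ensemble(ens: Ensemble, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": config_to_dict(ens.config),
        "fold_assignments": ens.fold_assignments,
        "n_members": len(ens.members),
        "ct_stats": asdict(ens.ct_stats) if ens.ct_stats else None,
    }
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2) + "\n")
    for k, m in enumerate(ens.members):
        np.savez(out / f"member_{k}.npz", **m.state_dict())


def load_ensemble(run_dir) -> Ensemble:
    run = Path(run_dir)
    meta = json.loads((run / "ensemble.json").read_text())
    cfg = config_from_dict(meta["config"])
    members = []
    for k in range(meta["n_members"]):
        net = build_network(cfg, seed=0)
        with np.load(run / f"member_{k}.npz") as st:
            net.load_state_dict(dict(st))
        members.append(net)
    stats = DatasetStats(**meta["ct_stats"]) if meta.get("ct_stats") else None
    return Ensemble(
        members=members,
        config=cfg,
        fold_assignments=meta["fold_assignments"],
        ct_stats=stats,
    )
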