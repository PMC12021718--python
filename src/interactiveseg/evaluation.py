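"""Segmentation agreement battery: overlap metrics (DSC, IOU,
sensitivity), volumetry, maximum transverse diameter, Bland-Altman
limits of agreement, Pearson correlation, and the paired Wilcoxon
signed-rank test, plus cohort report tables.

Conventions: empty-vs-empty overlap counts as perfect agreement (1.0),
since a prediction and reference can both be legitimately empty;
sensitivity against an empty reference is undefined and reported as NaN.
SD uses the n-1 denominator throughout; limits of agreement are
mean +/- 1.96 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .imaging import SegmentationMask


@dataclass
class MetricsRecord:
    case_id: str
    dsc: float
    iou: float
    sensitivity: float
    volume_mm3: float
    max_diameter_transverse_mm: float


@dataclass
class AgreementStats:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n: int


class GridMismatchError(ValueError):
    pass


def overlap_metrics(pred: SegmentationMask, ref: SegmentationMask):
    """(DSC, IOU, sensitivity) of a prediction against a reference.

    DSC = 2|P∩R| / (|P|+|R|), IOU = |P∩R| / |P∪R|,
    sensitivity = |P∩R| / |R|.
    """
    if pred.shape != ref.shape:
        raise GridMismatchError(f"grids differ: {pred.shape} vs {ref.shape}")
    p = pred.labels > 0
    r = ref.labels > 0
    inter = int(np.logical_and(p, r).sum())
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return 1.0, 1.0, 1.0
    union = np_ + nr - inter
    dsc = 2.0 * inter / (np_ + nr)
    iou = inter / union
    sensitivity = inter / nr if nr > 0 else float("nan")
    return dsc, iou, sensitivity


def volume_mm3(mask: SegmentationMask) -> float:
    """Foreground voxel count times the voxel volume."""
    return float(mask.count()) * float(np.prod(mask.spacing))


def max_diameter_transverse(mask: SegmentationMask) -> float:
    """Maximum in-plane (x, y) diameter over transverse slices, in mm.

    Per slice, the maximum center-to-center Euclidean distance between
    foreground voxels; the overall maximum across slices is returned.
    Empty or single-voxel masks give 0.
    """
    sx, sy = mask.spacing[0], mask.spacing[1]
    best = 0.0
    for z in range(mask.shape[2]):
        coords = np.argwhere(mask.labels[:, :, z] > 0).astype(np.float64)
        if len(coords) < 2:
            continue
        coords[:, 0] *= sx
        coords[:, 1] *= sy
        if len(coords) > 64:
            try:
                coords = coords[ConvexHull(coords).vertices]
            except QhullError:
                pass  # collinear points: brute force below
        best = max(best, float(pdist(coords).max()))
    return best


def bland_altman(a, b, mode: str = "percent", plot_path=None) -> AgreementStats:
    """Bland-Altman agreement between paired measurement lists.

    ``absolute`` differences are a - b; ``percent`` differences are
    100 (a - b) / pairwise mean.  Pearson r is computed on the raw
    (a, b) pairs.  Optionally writes the plot to ``plot_path``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    means = (a + b) / 2.0
    if mode == "absolute":
        diffs = a - b
    elif mode == "percent":
        with np.errstate(divide="ignore", invalid="ignore"):
            diffs = np.where(means != 0, 100.0 * (a - b) / means, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else float("nan")
    else:
        r = float(sps.pearsonr(a, b).statistic)
    out = AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        n=len(a),
    )
    if plot_path is not None:
        _bland_altman_plot(means, diffs, out, mode, plot_path)
    return out


def _bland_altman_plot(means, diffs, stats: AgreementStats, mode, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    for y, style in (
        (stats.mean_diff, "-"),
        (stats.loa_low, "--"),
        (stats.loa_high, "--"),
    ):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (%)" if mode == "percent" else "difference")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_wilcoxon_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p from the signed-rank distribution.

    ``ranks2`` are the (mid-)ranks doubled to integers; ``w2`` the
    doubled positive-rank sum.  Counts subsets by dynamic programming
    over achievable rank sums, equivalent to enumerating all 2^n sign
    assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        counts[r:] += counts[: total + 1 - r]
    n_assign = counts.sum()
    w2 = int(round(w2))
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_wilcoxon(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; ties get mid-ranks.  The exact
    distribution (all sign assignments) is used for n <= 25, the normal
    approximation with tie correction above.  All-zero differences give
    NaN (the test is undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan")
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    if n <= 25:
        return _exact_wilcoxon_p(np.round(ranks * 2), w_pos * 2)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of the rank sum
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cohort reporting


def case_metrics(
    case_id: str, pred: SegmentationMask, ref: SegmentationMask
) -> MetricsRecord:
    dsc, iou, sens = overlap_metrics(pred, ref)
    return MetricsRecord(
        case_id=case_id,
        dsc=dsc,
        iou=iou,
        sensitivity=sens,
        volume_mm3=volume_mm3(pred),
        max_diameter_transverse_mm=max_diameter_transverse(pred),
    )


def metrics_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "dsc": r.dsc,
                "iou": r.iou,
                "sensitivity": r.sensitivity,
                "volume_mm3": r.volume_mm3,
                "diameter_mm": r.max_diameter_transverse_mm,
            }
            for r in records
        ]
    )


def cohort_report(
    records_by_method: dict[str, list[MetricsRecord]],
    reference_records: list[MetricsRecord] | None = None,
    out_dir=None,
    bland_altman_mode: str = "percent",
) -> dict:
    """Cohort tables: per-method mean +/- SD of each metric, pairwise
    Wilcoxon tests on DSC between methods, and Bland-Altman agreement of
    volume/diameter against the reference measurements (when given).

    Returns a dict of DataFrames/objects; writes CSVs (and Bland-Altman
    plots) under ``out_dir`` when provided.
    """
    from pathlib import Path

    summary_rows = []
    for method, records in records_by_method.items():
        df = metrics_frame(records)
        for col in ("dsc", "iou", "sensitivity", "volume_mm3", "diameter_mm"):
            vals = df[col].dropna()
            summary_rows.append(
                {
                    "method": method,
                    "metric": col,
                    "mean": vals.mean() if len(vals) else float("nan"),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                    "n": len(vals),
                }
            )
    summary = pd.DataFrame(summary_rows)

    methods = list(records_by_method)
    test_rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            d1 = [r.dsc for r in records_by_method[m1]]
            d2 = [r.dsc for r in records_by_method[m2]]
            p = paired_wilcoxon(d1, d2) if len(d1) == len(d2) else float("nan")
            test_rows.append({"method_a": m1, "method_b": m2, "wilcoxon_p_dsc": p})
    tests = pd.DataFrame(test_rows)

    agreement_rows = []
    plots = {}
    if reference_records is not None:
        ref_vol = [r.volume_mm3 for r in reference_records]
        ref_dia = [r.max_diameter_transverse_mm for r in reference_records]
        for method, records in records_by_method.items():
            for name, pred_vals, ref_vals in (
                ("volume_mm3", [r.volume_mm3 for r in records], ref_vol),
                ("diameter_mm", [r.max_diameter_transverse_mm for r in records], ref_dia),
            ):
                if len(pred_vals) != len(ref_vals) or len(pred_vals) < 2:
                    continue
                plot_path = None
                if out_dir is not None:
                    plot_path = Path(out_dir) / f"bland_altman_{method}_{name}.png"
                    plots[(method, name)] = plot_path
                ba = bland_altman(
                    pred_vals, ref_vals, mode=bland_altman_mode, plot_path=plot_path
                )
                agreement_rows.append(
                    {
                        "method": method,
                        "measurement": name,
                        "mode": bland_altman_mode,
                        "mean_diff": ba.mean_diff,
                        "sd_diff": ba.sd_diff,
                        "loa_low": ba.loa_low,
                        "loa_high": ba.loa_high,
                        "pearson_r": ba.pearson_r,
                        "n": ba.n,
                    }
                )
    agreement = pd.DataFrame(agreement_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        tests.to_csv(out / "wilcoxon.csv", index=False)
        if len(agreement):
            agreement.to_csv(out / "agreement.csv", index=False)
    return {"summary": summary, "tests": tests, "agreement": agreement, "plots": plots}
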