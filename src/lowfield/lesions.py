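"""Lesion-level and volume-level evaluation.

Connected-component lesion identification, maximum in-plane diameter (Dmax),
overlap-based lesion matching with lesion-wise TPR/FDR, Dice, Bland-Altman
volume agreement with Pearson correlation, and ICC(2,1) inter-rater
reliability with its F-based 95% confidence interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial.distance import pdist

from .image import VolumeImage, as_bool_mask

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])


def label_components(mask: VolumeImage, connectivity: int = 26) -> tuple:
    """Deterministically labelled components (ordered by minimum raveled voxel
    index).  Returns (labels array, n_components)."""
    m = as_bool_mask(mask)
    labels, n = ndimage.label(m, structure=_structure(connectivity))
    if n == 0:
        return labels, 0
    # reorder by first-encountered voxel in C scan order
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labels], n


def dmax(voxel_indices: np.ndarray, spacing) -> float:
    """Maximum in-plane lesion diameter (mm).

    For each orthogonal plane family, take the per-slice maximum pairwise
    distance between voxel centres plus one in-plane voxel pitch (so a single
    voxel has diameter one pitch); return the maximum over all planes.  The
    added pitch is the larger of the two in-plane spacings.
    """
    idx = np.asarray(voxel_indices, dtype=float)
    if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] == 0:
        raise ValueError("voxel_indices must be a non-empty (n, 3) array")
    spacing = np.asarray(spacing, dtype=float)
    best = 0.0
    for ax in range(3):
        in_plane = [a for a in range(3) if a != ax]
        pitch = float(max(spacing[in_plane]))
        for level in np.unique(idx[:, ax]):
            pts = idx[idx[:, ax] == level][:, in_plane] * spacing[in_plane]
            if len(pts) == 1:
                span = 0.0
            else:
                if len(pts) > 400:
                    from scipy.spatial import ConvexHull

                    try:
                        pts = pts[ConvexHull(pts).vertices]
                    except Exception:
                        pass
                span = float(pdist(pts).max())
            best = max(best, span + pitch)
    return best


def connected_components(
    mask: VolumeImage,
    connectivity: int = 26,
    intensity_image: VolumeImage | None = None,
) -> pd.DataFrame:
    """Per-lesion table: id, voxel count, volume (ml), centroid (mm), mean
    normalized intensity (if an intensity image is given) and Dmax (mm)."""
    labels, n = label_components(mask, connectivity)
    vox_ml = mask.voxel_volume_mm3 / 1000.0
    spacing = mask.spacing
    rows = []
    for lid in range(1, n + 1):
        idx = np.argwhere(labels == lid)
        centroid_vox = idx.mean(axis=0)
        centroid_mm = mask.affine[:3, :3] @ centroid_vox + mask.affine[:3, 3]
        row = {
            "lesion_id": lid,
            "voxel_count": int(len(idx)),
            "volume_ml": float(len(idx) * vox_ml),
            "centroid_x_mm": float(centroid_mm[0]),
            "centroid_y_mm": float(centroid_mm[1]),
            "centroid_z_mm": float(centroid_mm[2]),
            "dmax_mm": dmax(idx, spacing),
        }
        if intensity_image is not None:
            if intensity_image.shape != mask.shape:
                raise ValueError("intensity image grid does not match mask")
            row["mean_norm_intensity"] = float(
                np.mean(np.asarray(intensity_image.data)[labels == lid])
            )
        rows.append(row)
    cols = [
        "lesion_id",
        "voxel_count",
        "volume_ml",
        "centroid_x_mm",
        "centroid_y_mm",
        "centroid_z_mm",
        "dmax_mm",
    ] + (["mean_norm_intensity"] if intensity_image is not None else [])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class MatchResult:
    """Lesion-wise matching: a reference lesion is a true positive iff at
    least one of its voxels overlaps the predicted mask; a predicted lesion
    with no reference overlap is a false positive."""

    tp_ids: list
    fn_ids: list
    fp_ids: list
    n_ref: int
    n_pred: int
    tpr: float
    fdr: float
    fdr_defined: bool
    ref_labels: np.ndarray = field(repr=False, default=None)
    pred_labels: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "tp_ids": list(map(int, self.tp_ids)),
            "fn_ids": list(map(int, self.fn_ids)),
            "fp_ids": list(map(int, self.fp_ids)),
            "n_ref": self.n_ref,
            "n_pred": self.n_pred,
            "tpr": self.tpr,
            "fdr": self.fdr,
            "fdr_defined": self.fdr_defined,
        }


def match_lesions(ref_mask: VolumeImage, pred_mask: VolumeImage, connectivity: int = 26) -> MatchResult:
    """TPR = TP/(TP+FN) over reference lesions; FDR = FP/(FP+TP_pred) over
    predicted lesions.  Masks must share a grid (resample with
    nearest-neighbour first if they do not)."""
    if not ref_mask.same_grid(pred_mask):
        raise ValueError(
            "masks are on different grids; resample one onto the other "
            "(nearest-neighbour) before matching"
        )
    ref_labels, n_ref = label_components(ref_mask, connectivity)
    pred_labels, n_pred = label_components(pred_mask, connectivity)
    pred_bool = pred_labels > 0
    ref_bool = ref_labels > 0

    tp_ids, fn_ids = [], []
    for lid in range(1, n_ref + 1):
        (tp_ids if np.any(pred_bool[ref_labels == lid]) else fn_ids).append(lid)
    fp_ids = [
        lid for lid in range(1, n_pred + 1) if not np.any(ref_bool[pred_labels == lid])
    ]
    tpr = len(tp_ids) / n_ref if n_ref else float("nan")
    if n_pred == 0:
        fdr, defined = float("nan"), False
    else:
        fdr, defined = len(fp_ids) / n_pred, True
    return MatchResult(
        tp_ids=tp_ids,
        fn_ids=fn_ids,
        fp_ids=fp_ids,
        n_ref=n_ref,
        n_pred=n_pred,
        tpr=tpr,
        fdr=fdr,
        fdr_defined=defined,
        ref_labels=ref_labels,
        pred_labels=pred_labels,
    )


def tpr_fdr_sweep(
    ref_table: pd.DataFrame,
    pred_table: pd.DataFrame,
    match: MatchResult,
    axis: str = "size_ml",
    thresholds=None,
) -> pd.DataFrame:
    """Lesion-wise TPR/FDR restricted to lesions whose size or normalized
    intensity exceeds each threshold (reference attribute gates TPR,
    predicted attribute gates FDR)."""
    col = {"size_ml": "volume_ml", "intensity_z": "mean_norm_intensity"}.get(axis)
    if col is None:
        raise ValueError("axis must be size_ml or intensity_z")
    if thresholds is None:
        thresholds = [0.0]
    for table, name in ((ref_table, "reference"), (pred_table, "predicted")):
        if len(table) and col not in table.columns:
            raise ValueError(f"{name} table lacks column {col!r}")
    tp = set(match.tp_ids)
    fp = set(match.fp_ids)
    rows = []
    for s in thresholds:
        ref_sel = ref_table[ref_table[col] > s] if len(ref_table) else ref_table
        pred_sel = pred_table[pred_table[col] > s] if len(pred_table) else pred_table
        n_ref, n_pred = len(ref_sel), len(pred_sel)
        tpr = (
            sum(1 for lid in ref_sel["lesion_id"] if lid in tp) / n_ref
            if n_ref
            else float("nan")
        )
        fdr = (
            sum(1 for lid in pred_sel["lesion_id"] if lid in fp) / n_pred
            if n_pred
            else float("nan")
        )
        rows.append(
            {
                "threshold": float(s),
                "tpr": tpr,
                "fdr": fdr,
                "n_ref": n_ref,
                "n_pred": n_pred,
                "empty_ref": n_ref == 0,
                "empty_pred": n_pred == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DiceResult:
    value: float
    both_empty: bool = False


def dice(mask_a: VolumeImage, mask_b: VolumeImage) -> DiceResult:
    """Dice-Sorensen overlap 2|X&Y|/(|X|+|Y|); two empty masks score 1
    (flagged as degenerate)."""
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks are on different grids; resample before Dice")
    a = as_bool_mask(mask_a)
    b = as_bool_mask(mask_b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return DiceResult(1.0, both_empty=True)
    return DiceResult(2.0 * int((a & b).sum()) / (na + nb))


@dataclass
class AgreementStats:
    pearson_r: float
    bias_ml: float
    sd_diff_ml: float
    sem_ml: float
    loa_low_ml: float
    loa_high_ml: float
    prop_bias_r: float
    prop_bias_defined: bool
    n_pairs: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def volume_agreement(vol_ref_ml, vol_pred_ml, sem_mode: str = "sd_over_sqrt2") -> AgreementStats:
    """Bland-Altman agreement of paired volumes, differences = pred - ref.

    Limits of agreement are bias +- 1.96 SD(d); SEM defaults to SD(d)/sqrt(2).
    The correlation of differences against pair means flags proportional bias
    (negative when the predicted arm over-measures small and under-measures
    large volumes).
    """
    ref = np.asarray(vol_ref_ml, dtype=float)
    pred = np.asarray(vol_pred_ml, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1 or len(ref) < 3:
        raise ValueError("need >= 3 paired volumes")
    if np.std(ref) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in one volume series")
    d = pred - ref
    means = (pred + ref) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    sem = sd / np.sqrt(2.0) if sem_mode == "sd_over_sqrt2" else sd
    if sem_mode not in ("sd_over_sqrt2", "sd"):
        raise ValueError("sem_mode must be sd_over_sqrt2 or sd")
    r = float(stats.pearsonr(ref, pred).statistic)
    if np.std(d) == 0 or np.std(means) == 0:
        prop_r, prop_defined = float("nan"), False
    else:
        prop_r, prop_defined = float(stats.pearsonr(means, d).statistic), True
    return AgreementStats(
        pearson_r=r,
        bias_ml=bias,
        sd_diff_ml=sd,
        sem_ml=float(sem),
        loa_low_ml=bias - 1.96 * sd,
        loa_high_ml=bias + 1.96 * sd,
        prop_bias_r=prop_r,
        prop_bias_defined=prop_defined,
        n_pairs=int(len(ref)),
    )


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, single-measure, absolute-agreement ICC(2,1)
    with the standard F-based confidence interval.

    ratings: n_subjects x k_raters, no missing cells.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D table (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else float("nan")

    if mse == 0 and msc == mse:  # perfect agreement: degenerate F statistics
        return ICCResult(1.0, 1.0, 1.0)

    # Shrout & Fleiss (1979) interval for ICC(2,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return ICCResult(float(icc), float("nan"), float("nan"))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den if v_den > 0 else (n - 1.0) * (k - 1.0)
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    ci_low = (n * (msr - f1 * mse)) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = (n * (f2 * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return ICCResult(float(icc), float(ci_low), float(ci_high))


def study_summary(
    ref_table: pd.DataFrame, pred_table: pd.DataFrame, match: MatchResult | None = None
) -> dict:
    """Per-study extrema (smallest/largest Dmax), total volumes and a
    patient-level detection flag (>= 1 true-positive lesion)."""
    out = {
        "n_ref": int(len(ref_table)),
        "n_pred": int(len(pred_table)),
        "total_vol_ref_ml": float(ref_table["volume_ml"].sum()) if len(ref_table) else 0.0,
        "total_vol_pred_ml": float(pred_table["volume_ml"].sum()) if len(pred_table) else 0.0,
        "ref_empty": len(ref_table) == 0,
    }
    for tag, table in (("ref", ref_table), ("pred", pred_table)):
        if len(table):
            out[f"smallest_dmax_{tag}_mm"] = float(table["dmax_mm"].min())
            out[f"largest_dmax_{tag}_mm"] = float(table["dmax_mm"].max())
        else:
            out[f"smallest_dmax_{tag}_mm"] = float("nan")
            out[f"largest_dmax_{tag}_mm"] = float("nan")
    if match is not None:
        out["any_lesion_detected"] = len(match.tp_ids) > 0
        out["tpr"] = match.tpr
        out["fdr"] = match.fdr
    return out
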