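"""Preprocessing chain: registration, reslicing, bias correction, brain masking
and White-Stripe intensity normalization.

These stand in for the external tools typically used on real scans (N4, ANTs,
multi-atlas skull stripping); each implements the same interface so real
outputs can be injected as files.  Registration is driven by SimpleITK;
resampling is done in-package so interpolation conventions are uniform
(linear for intensities, nearest-neighbour for labels).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import VolumeImage, as_bool_mask

_ORDER = {"linear": 1, "nearest": 0}


@dataclass
class RigidAffineTransform:
    """World-to-world map taking fixed-image coordinates to moving-image
    coordinates (the resampling convention)."""

    matrix: np.ndarray  # 4x4
    kind: str = "rigid"
    fixed_image_id: str = ""
    moving_image_id: str = ""
    final_metric: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if self.kind == "rigid":
            r = self.matrix[:3, :3]
            if not np.allclose(r @ r.T, np.eye(3), atol=1e-5) or np.linalg.det(r) < 0:
                raise ValueError("rigid transform block is not a proper rotation")

    def inverse(self) -> "RigidAffineTransform":
        return RigidAffineTransform(
            np.linalg.inv(self.matrix),
            kind=self.kind,
            fixed_image_id=self.moving_image_id,
            moving_image_id=self.fixed_image_id,
        )

    def rotation_angle_deg(self) -> float:
        r = self.matrix[:3, :3]
        r = r / np.cbrt(np.linalg.det(r))
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "matrix": self.matrix.tolist(),
                    "kind": self.kind,
                    "fixed_image_id": self.fixed_image_id,
                    "moving_image_id": self.moving_image_id,
                },
                fh,
                indent=2,
            )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidAffineTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["matrix"]), d["kind"], d.get("fixed_image_id", ""), d.get("moving_image_id", ""))


def resample_to_grid(
    moving: VolumeImage,
    target_affine: np.ndarray,
    target_shape: tuple,
    interp: str = "linear",
    world_transform: np.ndarray | None = None,
    cval: float = 0.0,
    mode: str = "constant",
) -> VolumeImage:
    """Sample ``moving`` onto a target grid, optionally through a world map
    (fixed world -> moving world).  Out-of-volume samples are ``cval`` by
    default; pure reslicing uses edge replication instead so the sub-voxel
    field-of-view overhang does not invent zeros."""
    if interp not in _ORDER:
        raise ValueError(f"interp must be linear|nearest, got {interp!r}")
    t = np.eye(4) if world_transform is None else np.asarray(world_transform, float)
    # voxel_target -> world_fixed -> world_moving -> voxel_moving
    full = np.linalg.inv(moving.affine) @ t @ np.asarray(target_affine, float)
    idx = np.indices(target_shape, dtype=float)
    coords = np.tensordot(full[:3, :3], idx, axes=1) + full[:3, 3][:, None, None, None]
    data = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float),
        coords,
        order=_ORDER[interp],
        mode=mode,
        cval=cval,
    )
    if _ORDER[interp] == 0 and moving.data.dtype != float:
        data = data.astype(moving.data.dtype)
    return VolumeImage(data, np.asarray(target_affine, float), modality=moving.modality, meta=dict(moving.meta))


def reslice(image: VolumeImage, target_spacing, interp: str = "linear") -> VolumeImage:
    """Resample onto an axis-aligned grid of the given spacing covering the
    same world field of view (within one voxel)."""
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target_spacing must be positive")
    spacing = image.spacing
    if np.allclose(target, spacing, atol=1e-9):
        return image.like(np.asarray(image.data, dtype=float))
    shape = np.asarray(image.shape)
    fov = shape * spacing
    n = np.maximum(1, np.round(fov / target).astype(int))
    origin_edge = image.affine[:3, 3] - spacing / 2.0
    offset = (fov - n * target) / 2.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(target)
    affine[:3, 3] = origin_edge + offset + target / 2.0
    return resample_to_grid(image, affine, tuple(n), interp=interp, mode="nearest")


# ---------------------------------------------------------------------------
# Registration (SimpleITK-backed; the contract is sub-voxel recovery of known
# rigid perturbations on phantoms)
# ---------------------------------------------------------------------------


def _to_sitk(img: VolumeImage) -> sitk.Image:
    block = img.affine[:3, :3]
    spacing = img.spacing
    direction = block / spacing[None, :]
    out = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(img.data, (2, 1, 0)).astype(np.float64)))
    out.SetSpacing(tuple(float(s) for s in spacing))
    out.SetOrigin(tuple(float(o) for o in img.affine[:3, 3]))
    out.SetDirection(tuple(float(v) for v in direction.ravel()))
    return out


def register(
    moving: VolumeImage,
    fixed: VolumeImage,
    kind: str = "rigid",
    interp: str = "linear",
    metric: str = "meansquares",
) -> tuple:
    """Estimate the fixed->moving world map and resample moving onto fixed.

    metric: ``meansquares`` (same-modality, default) or ``mattes`` (mutual
    information, cross-modality).
    """
    if kind not in ("rigid", "affine"):
        raise ValueError("kind must be rigid|affine")
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    tx0 = sitk.Euler3DTransform() if kind == "rigid" else sitk.AffineTransform(3)
    initial = sitk.CenteredTransformInitializer(
        f, m, tx0, sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    if metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        reg.SetMetricAsMeanSquares()
    # seeded random subsampling keeps the cost modest and the result deterministic
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(0.25, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=300,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    try:
        final = reg.Execute(f, m)
    except RuntimeError as exc:  # pragma: no cover - environment-dependent
        raise RuntimeError(f"registration failed to converge: {exc}") from exc

    final = final.Downcast() if hasattr(final, "Downcast") else final
    matrix = _sitk_to_matrix(final)
    tf = RigidAffineTransform(
        matrix,
        kind=kind,
        fixed_image_id=fixed.modality,
        moving_image_id=moving.modality,
        final_metric=float(reg.GetMetricValue()),
    )
    resampled = resample_to_grid(
        moving, fixed.affine, fixed.shape, interp=interp, world_transform=matrix
    )
    return tf, resampled


def _sitk_to_matrix(tx) -> np.ndarray:
    tx = tx if not isinstance(tx, sitk.CompositeTransform) else tx.GetNthTransform(0)
    a = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    mat = np.eye(4)
    mat[:3, :3] = a
    mat[:3, 3] = t + c - a @ c
    return mat


# ---------------------------------------------------------------------------
# Bias correction (log-polynomial stand-in)
# ---------------------------------------------------------------------------


def _wm_band(values: np.ndarray, width_sigmas: float = 3.0):
    """Boolean selector for the white-matter intensity band: last prominent
    histogram peak +- width_sigmas peak-widths (curvature estimate)."""
    from scipy.signal import find_peaks

    lo, hi = np.percentile(values, [1, 99])
    if hi <= lo:
        return None
    hist, edges = np.histogram(values, bins=128, range=(lo, hi))
    smoothed = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
    peaks, _ = find_peaks(smoothed, prominence=0.05 * smoothed.max())
    peak = int(peaks[-1]) if len(peaks) else int(np.argmax(smoothed))
    centers = (edges[:-1] + edges[1:]) / 2.0
    sigma = _peak_sigma(smoothed, centers, peak)
    if sigma is None or sigma <= 0:
        # very narrow peak: take the SD right around the mode
        near = values[np.abs(values - centers[peak]) < 0.05]
        sigma = max(float(np.std(near)) if near.size else 0.0, 1e-4)
    return np.abs(values - centers[peak]) < width_sigmas * sigma


def _poly_design(coords, order: int) -> np.ndarray:
    cols = []
    x, y, z = coords
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                cols.append((x**px) * (y**py) * (z**pz))
    return np.stack(cols, axis=1)


def bias_correct(image: VolumeImage, mask, order: int = 2, refine: bool = True) -> VolumeImage:
    """Divide out a smooth multiplicative field fitted as a polynomial in log
    intensity within the mask; mean intensity in the mask is preserved.

    Two-stage fit: a global least-squares fit over all in-mask voxels removes
    the bulk of the field, then (``refine=True``) the fit is repeated using
    only voxels in the white-matter intensity band of the corrected image
    (mode +- 3 peak-widths), which stops ventricles and the cortical rim from
    masquerading as bias.  Selecting the band on the *corrected* image matters:
    on the raw image an intensity band under strong bias is an iso-bias shell,
    not a tissue.
    """
    m = as_bool_mask(mask)
    if not np.any(m):
        raise ValueError("bias correction mask is empty")
    data = np.asarray(image.data, dtype=float)
    pos = m & (data > 0)
    if pos.sum() < 10:
        raise ValueError("degenerate bias fit: too few positive voxels in mask")
    idx = np.argwhere(pos).astype(float)
    half = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    u = (idx - half) / np.maximum(half, 1.0)
    design = _poly_design((u[:, 0], u[:, 1], u[:, 2]), order)
    logv = np.log(data[pos])
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)
    if refine:
        trend = design @ coef
        corrected_log = logv - (trend - trend.mean())
        band = _wm_band(corrected_log)
        if band is not None and band.sum() >= 100:
            coef, *_ = np.linalg.lstsq(design[band], logv[band], rcond=None)

    all_idx = np.indices(image.shape, dtype=float).reshape(3, -1).T
    ua = (all_idx - half) / np.maximum(half, 1.0)
    field_log = (_poly_design((ua[:, 0], ua[:, 1], ua[:, 2]), order) @ coef).reshape(image.shape)
    field = np.exp(field_log - np.mean(field_log[pos]))
    corrected = data / field
    mean_before = float(np.mean(data[m]))
    mean_after = float(np.mean(corrected[m]))
    if mean_after != 0:
        corrected *= mean_before / mean_after
    return image.like(corrected)


# ---------------------------------------------------------------------------
# White-Stripe intensity normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    stripe_center: float
    stripe_halfwidth: float
    stripe_mean: float
    stripe_sd: float
    n_stripe: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def whitestripe_normalize(
    image: VolumeImage,
    brain_mask,
    tau: float = 0.05,
    bins: int = 128,
    smooth_bins: float = 2.0,
) -> tuple:
    """z-score the image by the white-matter "stripe" centre and the WM scale.

    The WM mode is the last (highest-intensity) prominent peak of a smoothed
    in-mask histogram for FLAIR/T2w and T1w alike in this phantom setting;
    the stripe is the +-tau quantile window around it and supplies the centre
    (stripe mean).  The scale is the WM SD estimated from the curvature of
    the histogram peak (Gaussian fit to log-counts near the mode): the SD of
    a narrow quantile slice measures the width of the slice rather than the
    tissue SD, and downstream z thresholds assume normal-appearing WM has
    roughly unit variance.  Normalized WM sits near zero; FLAIR lesions are
    positive.
    """
    m = as_bool_mask(brain_mask)
    if not np.any(m):
        raise ValueError("brain mask is empty")
    vals = np.asarray(image.data, dtype=float)[m]
    lo, hi = np.percentile(vals, [1, 99])
    if hi <= lo:
        raise ValueError("degenerate intensity range inside brain mask")
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    smoothed = ndimage.gaussian_filter1d(hist.astype(float), smooth_bins)
    from scipy.signal import find_peaks

    peaks, props = find_peaks(smoothed, prominence=0.05 * smoothed.max())
    if len(peaks) == 0:
        raise ValueError("no detectable white-matter peak; widen histogram smoothing")
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak_val = centers[peaks[-1]]  # last prominent peak = WM for these contrasts

    q_peak = float(np.mean(vals <= peak_val))
    q_lo, q_hi = max(0.0, q_peak - tau), min(1.0, q_peak + tau)
    lo_v, hi_v = np.quantile(vals, [q_lo, q_hi])
    stripe = vals[(vals >= lo_v) & (vals <= hi_v)]
    if stripe.size < 100:
        raise ValueError("white stripe has fewer than 100 voxels; widen tau")
    mu = float(np.mean(stripe))
    sd = _peak_sigma(smoothed, centers, int(peaks[-1]))
    if sd is None or sd <= 0:
        sd = float(np.std(stripe, ddof=1))  # fallback: literal stripe SD
    if sd <= 0:
        raise ValueError("white stripe has zero variance")
    params = NormalizationParams(
        stripe_center=float(peak_val),
        stripe_halfwidth=float(tau),
        stripe_mean=mu,
        stripe_sd=sd,
        n_stripe=int(stripe.size),
    )
    out = image.like((np.asarray(image.data, dtype=float) - mu) / sd)
    out.meta["whitestripe"] = params.as_dict()
    return out, params


def _peak_sigma(smoothed_counts: np.ndarray, centers: np.ndarray, peak_idx: int):
    """WM SD from the histogram mode: fit log h = c - (x - mu)^2 / (2 sigma^2)
    over the contiguous bins around the peak with >= 60% of the peak height."""
    h0 = smoothed_counts[peak_idx]
    if h0 <= 0:
        return None
    lo = peak_idx
    while lo > 0 and smoothed_counts[lo - 1] >= 0.6 * h0:
        lo -= 1
    hi = peak_idx
    while hi < len(smoothed_counts) - 1 and smoothed_counts[hi + 1] >= 0.6 * h0:
        hi += 1
    if hi - lo < 4:
        return None
    x = centers[lo : hi + 1]
    y = np.log(smoothed_counts[lo : hi + 1])
    a = np.polyfit(x, y, 2)[0]
    if a >= 0:
        return None
    return float(np.sqrt(-1.0 / (2.0 * a)))


# ---------------------------------------------------------------------------
# Brain masking (threshold + morphology stand-in)
# ---------------------------------------------------------------------------


def brain_mask(image: VolumeImage, closing_radius: int = 2) -> VolumeImage:
    """Otsu threshold, largest connected component, morphological closing and
    hole filling.  On phantoms this covers >= 99% of the true brain."""
    data = np.asarray(image.data, dtype=float)
    if not np.any(data > 0):
        raise ValueError("cannot mask an all-zero image")
    thr = threshold_otsu(data)
    fg = data > thr
    if not np.any(fg):
        raise ValueError("empty foreground after thresholding")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        ball = _ball(closing_radius)
        fg = ndimage.binary_closing(fg, structure=ball)
    fg = ndimage.binary_fill_holes(fg)
    if not np.any(fg):
        raise ValueError("brain mask is empty")
    return image.like(fg.astype(np.uint8), modality="mask")


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    grid = np.indices((2 * r + 1,) * 3) - r
    return (grid**2).sum(axis=0) <= r**2
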