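"""Image-quality metrics: lesion conspicuity, SNR, CNR and Laplacian focus.

Conspicuity = (mu_L - mu_WM) / (mu_L + mu_WM)
SNR         = mu_L / sigma_AIR
CNR         = |mu_L - mu_WM| / sigma_AIR

where mu_L / mu_WM are mean intensities over lesion / normal-appearing white
matter ROIs and sigma_AIR is the sample SD (ddof=1) over an air ROI.  Image
sharpness is scored as the variance of a per-slice 2D discrete Laplacian
(a standard focus measure: blur suppresses second derivatives); the local
3x3x3 Laplacian-sum map is also available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VolumeImage, as_bool_mask

SLICE_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class RoiSet:
    """Lesion / NAWM / air regions on the target image's grid."""

    lesion: np.ndarray | None = None
    nawm: np.ndarray | None = None
    air: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("lesion", "nawm", "air"):
            m = getattr(self, name)
            if m is not None:
                setattr(self, name, as_bool_mask(m))
        pairs = [("lesion", "nawm"), ("lesion", "air"), ("nawm", "air")]
        for a, b in pairs:
            ma, mb = getattr(self, a), getattr(self, b)
            if ma is not None and mb is not None and np.any(ma & mb):
                raise ValueError(f"ROIs {a!r} and {b!r} overlap")

    def require(self, image: VolumeImage, *names) -> None:
        for name in names:
            m = getattr(self, name)
            if m is None or not np.any(m):
                raise ValueError(f"ROI {name!r} is empty or missing")
            if m.shape != image.shape:
                raise ValueError(f"ROI {name!r} does not match the image grid")


@dataclass
class QualityReport:
    conspicuity: float
    snr: float
    cnr: float
    focus_variance: float
    n_lesion: int
    n_nawm: int
    n_air: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _roi_mean(image: VolumeImage, mask: np.ndarray) -> float:
    return float(np.mean(image.data[mask]))


def conspicuity(image: VolumeImage, rois: RoiSet) -> float:
    """Normalized lesion-to-WM contrast, in [-1, 1] for non-negative images."""
    rois.require(image, "lesion", "nawm")
    mu_l = _roi_mean(image, rois.lesion)
    mu_wm = _roi_mean(image, rois.nawm)
    denom = mu_l + mu_wm
    if denom == 0:
        raise ValueError("conspicuity undefined: mu_L + mu_WM = 0")
    return (mu_l - mu_wm) / denom


def air_sd(image: VolumeImage, rois: RoiSet) -> float:
    rois.require(image, "air")
    if int(rois.air.sum()) < 2:
        raise ValueError("air ROI needs at least 2 voxels")
    return float(np.std(image.data[rois.air], ddof=1))


def snr(image: VolumeImage, rois: RoiSet) -> float:
    rois.require(image, "lesion", "air")
    sd = air_sd(image, rois)
    if sd == 0:
        raise ValueError("infinite SNR: air ROI has zero standard deviation")
    return _roi_mean(image, rois.lesion) / sd


def cnr(image: VolumeImage, rois: RoiSet) -> float:
    rois.require(image, "lesion", "nawm", "air")
    sd = air_sd(image, rois)
    if sd == 0:
        raise ValueError("infinite CNR: air ROI has zero standard deviation")
    return abs(_roi_mean(image, rois.lesion) - _roi_mean(image, rois.nawm)) / sd


_KERNEL_2D = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def laplacian_map(image: VolumeImage, slice_axis: str | int = "axial") -> VolumeImage:
    """Per-slice 2D 4-neighbour Laplacian, edge replication at borders."""
    ax = SLICE_AXIS_INDEX.get(slice_axis, slice_axis)
    if not isinstance(ax, int) or not 0 <= ax <= 2:
        raise ValueError(f"bad slice axis {slice_axis!r}")
    in_plane = [a for a in range(3) if a != ax]
    if any(image.shape[a] < 3 for a in in_plane):
        raise ValueError("image needs >= 3 voxels along each in-plane axis")
    kernel = np.expand_dims(_KERNEL_2D, axis=ax)
    lap = ndimage.convolve(np.asarray(image.data, dtype=float), kernel, mode="nearest")
    out = image.like(lap, modality="map")
    out.meta["slice_axis"] = int(ax)
    return out


def local_laplacian_sum(
    image: VolumeImage, slice_axis: str | int = "axial", window: int = 3
) -> VolumeImage:
    """Local focus map: Laplacian summed over a window x window in-plane
    neighbourhood and the slice above/below (3 slices)."""
    ax = SLICE_AXIS_INDEX.get(slice_axis, slice_axis)
    lap = laplacian_map(image, slice_axis=ax)
    size = [window, window, window]
    size[ax] = 3
    summed = ndimage.uniform_filter(lap.data, size=size, mode="nearest") * np.prod(size)
    return image.like(summed, modality="map")


def focus_score(
    image: VolumeImage,
    mask: np.ndarray | VolumeImage,
    slice_axis: str | int = "axial",
) -> float:
    """Variance (ddof=1) of the per-slice Laplacian inside the mask.

    Higher means sharper; Gaussian blur strictly lowers it on textured images.
    """
    m = as_bool_mask(mask)
    if int(m.sum()) < 2:
        raise ValueError("focus mask needs at least 2 voxels")
    lap = laplacian_map(image, slice_axis=slice_axis)
    return float(np.var(lap.data[m], ddof=1))


def default_air_roi(image: VolumeImage, box_frac: float = 0.12) -> np.ndarray:
    """Eight corner boxes of the volume, assumed outside the head."""
    mask = np.zeros(image.shape, dtype=bool)
    sizes = [max(1, int(round(n * box_frac))) for n in image.shape]
    for sx in (slice(0, sizes[0]), slice(-sizes[0], None)):
        for sy in (slice(0, sizes[1]), slice(-sizes[1], None)):
            for sz in (slice(0, sizes[2]), slice(-sizes[2], None)):
                mask[sx, sy, sz] = True
    return mask


def quality_report(
    image: VolumeImage, rois: RoiSet, focus_mask=None, slice_axis="axial"
) -> QualityReport:
    fm = rois.nawm if focus_mask is None else as_bool_mask(focus_mask)
    return QualityReport(
        conspicuity=conspicuity(image, rois),
        snr=snr(image, rois),
        cnr=cnr(image, rois),
        focus_variance=focus_score(image, fm, slice_axis=slice_axis),
        n_lesion=int(rois.lesion.sum()),
        n_nawm=int(rois.nawm.sum()),
        n_air=int(rois.air.sum()),
    )
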