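"""Segmentation harness: probability-map thresholding plus a built-in
intensity-based stand-in segmenter.

The package treats lesion segmentation as an external probability-map
producer (real pipelines use coupled-modality models such as MIMoSA);
``threshold_probability`` is the downstream contract, with the study's 0.2
cut as default.  ``naive_segment`` is a self-contained stand-in: a logistic
squashing of the (lightly smoothed) White-Stripe z-map of FLAIR.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import VolumeImage, as_bool_mask


def validate_probability_map(pmap: VolumeImage) -> VolumeImage:
    data = np.asarray(pmap.data, dtype=float)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return pmap


def threshold_probability(pmap: VolumeImage, t: float = 0.2) -> VolumeImage:
    """Binary mask = (p >= t).  Voxel count is non-increasing in t."""
    if not 0 < t < 1:
        raise ValueError("threshold must lie in (0, 1)")
    validate_probability_map(pmap)
    mask = (np.asarray(pmap.data, dtype=float) >= t).astype(np.uint8)
    out = pmap.like(mask, modality="mask")
    out.meta["threshold"] = float(t)
    return out


def despeckle(mask: VolumeImage, min_voxels: int = 3, connectivity: int = 26) -> VolumeImage:
    """Remove connected components smaller than min_voxels."""
    m = as_bool_mask(mask)
    if min_voxels <= 1 or not np.any(m):
        return mask.like(m.astype(np.uint8), modality="mask")
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labels, n = ndimage.label(m, structure=structure)
    if n == 0:
        return mask.like(m.astype(np.uint8), modality="mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_voxels])
    return mask.like(keep[labels].astype(np.uint8), modality="mask")


def naive_segment(
    flair_norm: VolumeImage,
    brain_mask,
    z_cut: float = 1.5,
    scale: float = 0.1,
    smooth_fwhm_vox: float = 2.0,
    min_voxels: int = 3,
) -> VolumeImage:
    """Stand-in lesion probability map from normalized FLAIR.

    probability = logistic((z_s - z_cut) / scale) inside the brain mask and
    zero outside, where z_s is the White-Stripe z-map smoothed with a small
    in-mask Gaussian (FWHM ``smooth_fwhm_vox`` voxels; 0 disables smoothing).
    The smoothing plays the role of the spatial regularization a trained
    probability-map producer provides: without it, thresholding a unit-variance
    noise map at z ~ 1.4 fires on ~8% of noise voxels at any field strength.
    ``min_voxels`` is the despeckling floor applied by downstream thresholding
    (stored in metadata).
    """
    if "whitestripe" not in flair_norm.meta:
        raise ValueError(
            "input is not White-Stripe normalized (no stripe parameters in metadata)"
        )
    m = as_bool_mask(brain_mask)
    z = np.asarray(flair_norm.data, dtype=float)
    if smooth_fwhm_vox > 0:
        sigma = smooth_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = m.astype(float)
        num = ndimage.gaussian_filter(z * w, sigma)
        den = ndimage.gaussian_filter(w, sigma)
        z = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)
    arg = np.clip((z - z_cut) / scale, -60.0, 60.0)
    prob = 1.0 / (1.0 + np.exp(-arg))
    prob[~m] = 0.0
    out = flair_norm.like(prob, modality="pmap")
    out.meta["segmenter"] = {
        "z_cut": float(z_cut),
        "scale": float(scale),
        "smooth_fwhm_vox": float(smooth_fwhm_vox),
        "min_voxels": int(min_voxels),
    }
    return out


def segment_flair(
    flair_norm: VolumeImage,
    brain_mask,
    threshold: float = 0.2,
    z_cut: float = 1.5,
    scale: float = 0.1,
    smooth_fwhm_vox: float = 2.0,
    min_voxels: int = 3,
    connectivity: int = 26,
) -> VolumeImage:
    """Convenience: stand-in probability map -> threshold -> despeckle."""
    pmap = naive_segment(
        flair_norm,
        brain_mask,
        z_cut=z_cut,
        scale=scale,
        smooth_fwhm_vox=smooth_fwhm_vox,
        min_voxels=min_voxels,
    )
    mask = threshold_probability(pmap, t=threshold)
    return despeckle(mask, min_voxels=min_voxels, connectivity=connectivity)
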