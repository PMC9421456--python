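"""Reproducible experiment protocols over the simulation pipeline.

Each function runs a self-contained study on synthetic anatomy and returns
the measured quantities; they are shared between the analysis scripts and
the acceptance checks so both execute exactly the same protocol.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .harmonize import brain_mask, register
from .image import VolumeImage
from .phantom import (
    PRESETS,
    AcquisitionSpec,
    LesionSpec,
    PhantomSpec,
    build_phantom,
    simulate_acquisition,
    spawn_seeds,
)
from .quality import RoiSet, focus_score, snr
from .superres import average_iterative, stable_air_roi, subslice_lesion_experiment


def _lesion_truth(seed: int = 0) -> "PhantomSpec":
    return PhantomSpec(
        lesions=[
            LesionSpec(
                center=(25.5, -20.5, 10.5),
                semi_axes=(5.0, 5.0, 5.0),
                contrast={"FLAIR": 0.25, "T1w": -0.15},
            )
        ],
        texture_seed=seed,
    )


def rayleigh_air_ratio(seed: int, noise_sigma: float = 0.05) -> dict:
    """SD of signal-free (air) magnitude noise over the channel sigma.

    Rician magnitude noise reduces to a Rayleigh distribution in air, whose
    SD is sigma * sqrt((4 - pi)/2) ~ 0.655 sigma.
    """
    truth = build_phantom(_lesion_truth())
    acq = AcquisitionSpec(target_spacing=(1, 1, 1), noise_sigma=noise_sigma)
    out = simulate_acquisition(truth.images["FLAIR"], acq, seed=seed)
    air = truth.air_mask.data.astype(bool)
    return {
        "ratio": float(out.data[air].std(ddof=1) / noise_sigma),
        "expected": float(np.sqrt((4 - np.pi) / 2)),
        "n_air_voxels": int(air.sum()),
    }


def snr_averaging_gain(seed: int, noise_sigma: float = 0.05) -> dict:
    """SNR of n-average acquisitions relative to a single excitation."""
    truth = build_phantom(_lesion_truth())
    rois = RoiSet(
        lesion=truth.lesion_mask.data,
        nawm=truth.nawm_mask.data,
        air=truth.air_mask.data,
    )
    values = {}
    for n in (1, 2, 4, 8):
        acq = AcquisitionSpec(target_spacing=(1, 1, 1), noise_sigma=noise_sigma, n_averages=n)
        values[n] = snr(simulate_acquisition(truth.images["FLAIR"], acq, seed=seed), rois)
    return {
        "snr_by_n": values,
        "gain_4_vs_1": values[4] / values[1],
        "gain_8_vs_1": values[8] / values[1],
    }


def sr_noise_sd_curve(seed: int, n_acquisitions: int = 8) -> dict:
    """Air-noise SD through the iterative reslice-register-average pipeline.

    Nearest-neighbour interpolation is used so resampling does not attenuate
    the voxel-wise noise and the sqrt(N) averaging law is isolated.
    """
    truth = build_phantom(PhantomSpec(texture_seed=seed))
    base = replace(PRESETS["64mt_flair_sr"], bias_amplitude=0.0)
    first = replace(base, reposition_max_rot_deg=0.0, reposition_max_trans_mm=0.0)
    seeds = spawn_seeds(seed, n_acquisitions)
    acqs = [simulate_acquisition(truth.images["FLAIR"], first, seeds[0])]
    acqs += [simulate_acquisition(truth.images["FLAIR"], base, s) for s in seeds[1:]]
    res = average_iterative(acqs, 1.8, interp="nearest")
    roi = stable_air_roi(res.averaged_volumes[0], truth.air_mask)
    sds = [float(v.data[roi].std(ddof=1)) for v in res.averaged_volumes]
    return {
        "sds": sds,
        "ratio_first_last": sds[0] / sds[-1],
        "expected": float(np.sqrt(len(sds))),
        "n_air_voxels": int(roi.sum()),
    }


def focus_blur_curve(sigmas=(0.0, 0.5, 1.0, 2.0)) -> list:
    """Laplacian focus of one phantom under increasing Gaussian blur."""
    from scipy import ndimage

    truth = build_phantom(_lesion_truth())
    img = truth.images["FLAIR"]
    mask = truth.tissue_labels.data > 0
    return [
        float(focus_score(img.like(ndimage.gaussian_filter(img.data, s)), mask))
        for s in sigmas
    ]


def focus_field_comparison(seed: int, n_replicates: int = 10) -> dict:
    """Per-replicate focus of the high-field scan registered and resliced to
    the low-field grid versus the low-field scan itself."""
    from .cohort import StudyConfig, sample_phantom_spec
    from .phantom import simulate_paired_study

    cfg = StudyConfig()
    rows = []
    for s in spawn_seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        spec = sample_phantom_spec(cfg, rng)
        study = simulate_paired_study(
            spec, PRESETS[cfg.highfield_preset], PRESETS[cfg.lowfield_preset], seed=s
        )
        hf, lf = study.highfield["FLAIR"], study.lowfield["FLAIR"]
        _, hf_on_lf = register(hf, lf, kind="rigid", interp="linear")
        bm = brain_mask(lf).data.astype(bool)
        rows.append(
            {
                "focus_hf_resliced": float(focus_score(hf_on_lf, bm)),
                "focus_lf": float(focus_score(lf, bm)),
            }
        )
    wins = sum(r["focus_hf_resliced"] > r["focus_lf"] for r in rows)
    return {"replicates": rows, "hf_wins": int(wins), "n": n_replicates}


def sr_conspicuity_replicates(seed: int, n_replicates: int = 5, detect: bool = True) -> dict:
    """Replicated sub-slice-lesion averaging runs; per-N mean conspicuity and
    detection flags."""
    curves, detections = [], []
    for s in spawn_seeds(seed, n_replicates):
        ex = subslice_lesion_experiment(int(s) or 1, detect=detect)
        curves.append([c["conspicuity"] for c in ex["result"].conspicuity_curve])
        if detect:
            detections.append(ex["detections"])
    curves = np.asarray(curves)
    return {
        "curves": curves,
        "mean_curve": curves.mean(axis=0).tolist(),
        "se_curve": (curves.std(axis=0, ddof=1) / np.sqrt(len(curves))).tolist(),
        "detections": detections,
    }


def preset_voxel_volume_ratio() -> float:
    """Low-field over high-field FLAIR voxel volume (prints as "about 13")."""
    hf = PRESETS["3t_flair"]
    lf = PRESETS["64mt_flair"]
    return float(np.prod(lf.target_spacing) / np.prod(hf.target_spacing))
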