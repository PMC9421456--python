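"""Cohort orchestration: simulate N paired studies, run the full
harmonize -> segment -> evaluate pipeline on each, and aggregate.

Mirrors the shape of a paired high-field / low-field patient study at
simulation scale: per-study smallest/largest detected lesion diameters by
field strength, total-volume correlation and Bland-Altman agreement,
Dice distribution, patient-level sensitivity, and lesion-wise TPR/FDR
sweeps by size and intensity.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import lesions as le
from .harmonize import bias_correct, brain_mask, register, resample_to_grid, whitestripe_normalize
from .image import VolumeImage
from .phantom import (
    PRESETS,
    AcquisitionSpec,
    LesionSpec,
    PhantomSpec,
    _rigid_world_matrix,
    simulate_paired_study,
    spawn_seeds,
)
from .segment import segment_flair

log = logging.getLogger("lowfield")


@dataclass
class StudyConfig:
    """Everything needed to reproduce a cohort run bit-for-bit."""

    n_studies: int = 20
    seed: int = 0
    highfield_preset: str = "3t_flair"
    lowfield_preset: str = "64mt_flair"
    # phantom population
    n_lesions_min: int = 5
    n_lesions_max: int = 9
    n_large_min: int = 1
    n_large_max: int = 4
    diameter_min_mm: float = 2.0
    diameter_max_mm: float = 12.0
    large_diameter_min_mm: float = 10.0
    large_diameter_max_mm: float = 20.0
    punctate_diameter_max_mm: float = 2.8  # every study gets one punctate lesion
    contrast_min: float = 0.18
    contrast_max: float = 0.32
    # segmentation
    prob_threshold: float = 0.2
    z_cut: float = 1.5
    logistic_scale: float = 0.1
    smooth_fwhm_vox: float = 2.0
    min_voxels: int = 3
    # evaluation
    connectivity: int = 26
    size_thresholds: tuple = (0.0, 0.25, 0.5, 1.0, 1.5, 2.5)
    intensity_thresholds: tuple = (0.0, 2.0, 4.0, 8.0)
    outdir: str = "results/cohort"
    make_plots: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def sample_phantom_spec(config: StudyConfig, rng: np.random.Generator) -> PhantomSpec:
    """Draw one study's lesion population on the default head geometry.

    Each study carries ``n_large_lesions`` guaranteed-large lesions (so every
    simulated patient has a confluent-scale lesion, as MS cohorts with
    established disease do) plus a random number of lesions with log-uniform
    diameters down to 2 mm.
    """
    base = PhantomSpec()
    n_small = int(rng.integers(config.n_lesions_min, config.n_lesions_max + 1))
    n_large = int(rng.integers(config.n_large_min, config.n_large_max + 1))
    diam_large = rng.uniform(
        config.large_diameter_min_mm, config.large_diameter_max_mm, n_large
    )
    diam_small = np.exp(
        rng.uniform(np.log(config.diameter_min_mm), np.log(config.diameter_max_mm), n_small)
    )
    # one guaranteed punctate lesion per study (MS cohorts with established
    # disease essentially always carry punctate foci; it anchors the
    # smallest-lesion statistics)
    diam_punctate = rng.uniform(config.diameter_min_mm, config.punctate_diameter_max_mm, 1)
    diameters = np.concatenate([diam_large, diam_small, diam_punctate])
    lesions: list[LesionSpec] = []
    brain = np.asarray(base.brain_semi_axes)
    for d in diameters:
        semi = d / 2.0 * rng.uniform(0.8, 1.2, 3)
        semi = np.clip(semi, 0.8, None)
        rmax = float(semi.max())
        placed = False
        for _ in range(300):
            u = rng.uniform(-1, 1, 3)
            center = u * (brain - rmax - 4.0)
            if np.sum((center / (brain - rmax - 2.0)) ** 2) > 1.0:
                continue
            # stay clear of the ventricles and existing lesions
            clear = True
            for vc, vs in base.ventricles:
                if np.sum(((center - np.asarray(vc)) / (np.asarray(vs) + rmax + 1.0)) ** 2) <= 1.0:
                    clear = False
                    break
            for other in lesions:
                gap = np.linalg.norm(center - np.asarray(other.center))
                if gap < rmax + max(other.semi_axes) + 2.0:
                    clear = False
                    break
            if clear:
                c = float(rng.uniform(config.contrast_min, config.contrast_max))
                lesions.append(
                    LesionSpec(
                        center=tuple(center),
                        semi_axes=tuple(semi),
                        contrast={"FLAIR": c, "T2w": 0.8 * c, "T1w": -0.6 * c},
                    )
                )
                placed = True
                break
        if not placed:
            log.warning("could not place a %.1f mm lesion; dropping it", d)
    return PhantomSpec(lesions=lesions)


def _truth_labels_on_grid(truth_labels: VolumeImage, acq_image: VolumeImage) -> VolumeImage:
    """Map the truth lesion-id volume onto an acquisition grid through the
    known repositioning transform recorded in the acquisition's provenance."""
    acq = acq_image.meta.get("acquisition", {})
    world = _rigid_world_matrix(
        acq.get("reposition_angles_deg", (0, 0, 0)),
        acq.get("reposition_trans_mm", (0, 0, 0)),
    )
    return resample_to_grid(
        truth_labels,
        acq_image.affine,
        acq_image.shape,
        interp="nearest",
        world_transform=np.linalg.inv(world),
    )


def _field_pipeline(image: VolumeImage, config: StudyConfig):
    """brain mask -> bias correction -> White Stripe -> stand-in segmentation."""
    bm = brain_mask(image)
    bc = bias_correct(image, bm, order=2)
    norm, _ = whitestripe_normalize(bc, bm)
    seg = segment_flair(
        norm,
        bm,
        threshold=config.prob_threshold,
        z_cut=config.z_cut,
        scale=config.logistic_scale,
        smooth_fwhm_vox=config.smooth_fwhm_vox,
        min_voxels=config.min_voxels,
        connectivity=config.connectivity,
    )
    return bm, bc, norm, seg


def _truth_detection(truth_table, truth_labels_grid: VolumeImage, seg: VolumeImage):
    """Per truth lesion: detected iff >= 1 voxel of its (repositioned) support
    overlaps the segmentation.  Returns (detected ids, smallest detected Dmax)."""
    lab = np.asarray(truth_labels_grid.data)
    segm = np.asarray(seg.data) > 0
    detected = []
    for _, row in truth_table.iterrows():
        lid = int(row["lesion_id"])
        support = lab == lid + 1
        if support.any() and np.any(segm & support):
            detected.append(lid)
    if detected:
        dmaxes = truth_table.set_index("lesion_id").loc[detected, "dmax_mm"]
        smallest = float(dmaxes.min())
    else:
        smallest = float("nan")
    return detected, smallest


def run_study(config: StudyConfig, study_seed: int, study_id: int) -> dict:
    rng = np.random.default_rng(study_seed)
    phantom = sample_phantom_spec(config, rng)
    study = simulate_paired_study(
        phantom,
        PRESETS[config.highfield_preset],
        PRESETS[config.lowfield_preset],
        seed=study_seed,
    )
    hf_img = study.highfield["FLAIR"]
    lf_img = study.lowfield["FLAIR"]

    _, hf_bc, hf_norm, hf_seg = _field_pipeline(hf_img, config)
    _, lf_bc, lf_norm, lf_seg = _field_pipeline(lf_img, config)

    hf_table = le.connected_components(hf_seg, config.connectivity, intensity_image=hf_norm)
    lf_table = le.connected_components(lf_seg, config.connectivity, intensity_image=lf_norm)

    # truth-referenced detection per field (known repositioning, no estimation)
    truth_tab = study.truth.lesion_table
    hf_truth_lab = _truth_labels_on_grid(study.truth.lesion_labels, hf_img)
    lf_truth_lab = _truth_labels_on_grid(study.truth.lesion_labels, lf_img)
    hf_det, hf_smallest = _truth_detection(truth_tab, hf_truth_lab, hf_seg)
    lf_det, lf_smallest = _truth_detection(truth_tab, lf_truth_lab, lf_seg)

    # paired-field comparison on the low-field grid (estimated registration)
    tf, _ = register(hf_bc, lf_bc, kind="rigid", interp="linear")
    hf_seg_on_lf = resample_to_grid(
        hf_seg, lf_seg.affine, lf_seg.shape, interp="nearest", world_transform=tf.matrix
    )
    pair_match = le.match_lesions(hf_seg_on_lf, lf_seg, config.connectivity)
    pair_dice = le.dice(hf_seg_on_lf, lf_seg)

    fine_vox_ml = study.truth.lesion_mask.voxel_volume_mm3 / 1000.0
    truth_total = float(truth_tab["voxel_count"].sum() * fine_vox_ml)
    sub5 = truth_tab["dmax_mm"] < 5.0

    return {
        "study_id": study_id,
        "seed": study_seed,
        "n_truth_lesions": int(len(truth_tab)),
        "truth_total_vol_ml": truth_total,
        "truth_smallest_dmax_mm": float(truth_tab["dmax_mm"].min()),
        "has_sub5mm_lesion": bool(sub5.any()),
        "hf_total_vol_ml": float(hf_table["volume_ml"].sum()) if len(hf_table) else 0.0,
        "lf_total_vol_ml": float(lf_table["volume_ml"].sum()) if len(lf_table) else 0.0,
        "hf_n_detected": len(hf_det),
        "lf_n_detected": len(lf_det),
        "hf_smallest_detected_dmax_mm": hf_smallest,
        "lf_smallest_detected_dmax_mm": lf_smallest,
        "lf_any_lesion_detected": len(lf_det) > 0,
        "hf_any_lesion_detected": len(hf_det) > 0,
        "dice_hf_lf": pair_dice.value,
        "pair_tpr": pair_match.tpr,
        "pair_fdr": pair_match.fdr,
        "_tables": {"hf": hf_table, "lf": lf_table, "truth": truth_tab},
        "_match": pair_match,
    }


def run_cohort(config: StudyConfig) -> dict:
    """Simulate and evaluate the whole cohort; returns per-study table and
    aggregate statistics.  A failed study is flagged and excluded."""
    from scipy import stats as sps

    seeds = spawn_seeds(config.seed, config.n_studies)
    rows, failures = [], []
    sweeps = []
    for i, s in enumerate(seeds):
        try:
            res = run_study(config, s, i)
        except Exception as exc:  # noqa: BLE001 - study-level exclusion mirror
            log.exception("study %d failed", i)
            failures.append({"study_id": i, "seed": s, "reason": str(exc)})
            continue
        tabs, match = res.pop("_tables"), res.pop("_match")
        for axis, thr in (
            ("size_ml", config.size_thresholds),
            ("intensity_z", config.intensity_thresholds),
        ):
            sw = le.tpr_fdr_sweep(tabs["hf"], tabs["lf"], match, axis=axis, thresholds=list(thr))
            sw.insert(0, "study_id", i)
            sw.insert(1, "axis", axis)
            sweeps.append(sw)
        rows.append(res)

    df = pd.DataFrame(rows)
    df["config_hash"] = config.config_hash()
    df["cohort_seed"] = config.seed
    sweep_df = pd.concat(sweeps, ignore_index=True) if sweeps else pd.DataFrame()

    agg: dict = {
        "n_studies": int(len(df)),
        "n_failed": len(failures),
        "patient_level_sensitivity_lf": float(df["lf_any_lesion_detected"].mean()) if len(df) else float("nan"),
        "patient_level_sensitivity_hf": float(df["hf_any_lesion_detected"].mean()) if len(df) else float("nan"),
        "mean_smallest_detected_dmax_hf_mm": float(df["hf_smallest_detected_dmax_mm"].mean()),
        "mean_smallest_detected_dmax_lf_mm": float(df["lf_smallest_detected_dmax_mm"].mean()),
        "dice_mean": float(df["dice_hf_lf"].mean()),
        "dice_sd": float(df["dice_hf_lf"].std(ddof=1)),
    }
    if len(df) >= 3:
        agg["truth_vs_hf_volume_pearson_r"] = float(
            sps.pearsonr(df["truth_total_vol_ml"], df["hf_total_vol_ml"]).statistic
        )
        agg["truth_vs_lf_volume_pearson_r"] = float(
            sps.pearsonr(df["truth_total_vol_ml"], df["lf_total_vol_ml"]).statistic
        )
        agreement = le.volume_agreement(df["hf_total_vol_ml"], df["lf_total_vol_ml"])
        agg["hf_vs_lf_agreement"] = agreement.as_dict()
        agg["dice_vs_volume_spearman"] = float(
            sps.spearmanr(df["hf_total_vol_ml"], df["dice_hf_lf"]).statistic
        )
    sub = df[df["has_sub5mm_lesion"] & df["lf_any_lesion_detected"] & df["hf_any_lesion_detected"]]
    if len(sub):
        agg["frac_sub5mm_studies_lf_smallest_gt_hf"] = float(
            np.mean(
                sub["lf_smallest_detected_dmax_mm"] > sub["hf_smallest_detected_dmax_mm"]
            )
        )
    return {"studies": df, "sweeps": sweep_df, "aggregate": agg, "failures": failures}


def write_cohort_report(result: dict, config: StudyConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["studies"].to_csv(outdir / "studies.csv", index=False)
    if len(result["sweeps"]):
        result["sweeps"].to_csv(outdir / "tpr_fdr_sweeps.csv", index=False)
    with open(outdir / "aggregate.json", "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "config_hash": config.config_hash(),
                "aggregate": result["aggregate"],
                "failures": result["failures"],
            },
            fh,
            indent=2,
            default=float,
        )
    if config.make_plots:
        _plots(result, outdir)
    return outdir


def _plots(result: dict, outdir: Path) -> None:  # pragma: no cover - cosmetic
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result["studies"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    m = (df["hf_total_vol_ml"] + df["lf_total_vol_ml"]) / 2
    d = df["lf_total_vol_ml"] - df["hf_total_vol_ml"]
    axes[0].scatter(m, d)
    axes[0].axhline(d.mean(), ls="--")
    axes[0].set_xlabel("mean volume (ml)")
    axes[0].set_ylabel("LF - HF (ml)")
    axes[0].set_title("Bland-Altman")
    axes[1].scatter(df["hf_total_vol_ml"], df["dice_hf_lf"])
    axes[1].set_xlabel("HF total volume (ml)")
    axes[1].set_ylabel("Dice")
    fig.tight_layout()
    fig.savefig(outdir / "cohort_summary.png", dpi=120)
    plt.close(fig)
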