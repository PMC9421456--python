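# lowfield-lesion

Simulation and evaluation toolkit for comparing white-matter-lesion (WML)
imaging between conventional high-field (3T-like, 1 mm isotropic FLAIR) and
portable low-field (64 mT-like, 1.6 × 1.6 × 5 mm FLAIR) brain MRI.

Portable low-field scanners trade spatial resolution and signal-to-noise for
accessibility; whether they can support multiple-sclerosis lesion monitoring
hinges on quantitative questions — how small a lesion survives a 13× larger
voxel, how total lesion volume estimates agree across field strengths, and
how much repeated-acquisition averaging buys back. Real paired patient scans
are rarely shareable, so this package provides a fully synthetic, ground-truth
paired pipeline: a digital brain phantom with controllable lesions, a
physics-based acquisition model, preprocessing and segmentation stand-ins,
and the lesion-level statistics used to compare the two field strengths.

## What is implemented

- **Phantom + forward model** (`lowfield.phantom`): ellipsoidal head with
  ventricles, cortical rim, textured white matter and ellipsoidal lesions
  (FLAIR/T2w-hyperintense, T1w-hypointense, per-lesion target conspicuity).
  Acquisition rendering = rigid repositioning ∘ PSF blur ∘ partial-volume
  block averaging onto the scanner grid ∘ multiplicative bias field ∘ Rician
  magnitude noise (n-average), with an optional in-plane reconstruction
  filter. Presets mirror the study geometries (`3t_flair`, `64mt_flair`,
  orthogonal variants, `64mt_flair_sr`).
- **Image quality** (`lowfield.quality`):
  conspicuity = (μ_L − μ_WM)/(μ_L + μ_WM), SNR = μ_L/σ_air,
  CNR = |μ_L − μ_WM|/σ_air, and image sharpness as the variance of a
  per-slice 2D Laplacian (with the local 3×3×3 Laplacian-sum map available).
- **Preprocessing** (`lowfield.harmonize`): rigid/affine registration
  (SimpleITK-backed, sub-voxel contract verified on phantoms), reslicing,
  polynomial bias-field correction, Otsu+morphology brain masking, and
  White-Stripe intensity normalization (z-scoring by the white-matter mode).
- **Segmentation harness** (`lowfield.segment`): thresholding of external
  lesion-probability maps at p ≥ 0.2 plus a built-in logistic-of-z stand-in
  segmenter so the pipeline runs end-to-end without external tools.
- **Lesion evaluation** (`lowfield.lesions`): connected components, maximum
  in-plane diameter (Dmax), ≥1-voxel-overlap lesion matching with lesion-wise
  TPR = TP/(TP+FN) and FDR = FP/(FP+TP), TPR/FDR sweeps by lesion size and
  normalized intensity, Dice overlap, Bland–Altman volume agreement, and
  ICC(2,1) with its F-based 95 % CI.
- **Super-resolution** (`lowfield.superres`): iterative multi-acquisition
  averaging with repositioning (reslice → affine-register to first → running
  mean) and orthogonal-plane fusion to an isotropic grid.
- **Cohort orchestration** (`lowfield.cohort`) and a `lowfield` CLI with
  `simulate`, `quality`, `segment`, `evaluate`, `superres`, `cohort`
  subcommands.

The analyses themselves live as numbered drivers under `analysis/`
(01 simulate a paired study, 02 image quality, 03 cohort evaluation,
04 iterative averaging, 05 orthogonal fusion); each writes its tables under
`results/`.

## Worked example

```bash
python analysis/03_cohort_analysis.py
```

simulates 20 paired studies and evaluates both arms; with the default
configuration and seed it prints (abbreviated):

```
"mean_smallest_detected_dmax_hf_mm": 2.59,
"mean_smallest_detected_dmax_lf_mm": 6.34,
"patient_level_sensitivity_lf": 1.0,
"dice_mean": 0.59,
"truth_vs_hf_volume_pearson_r": 0.98,
"hf_vs_lf_agreement": {"pearson_r": 0.94, "bias_ml": -2.30,
                       "prop_bias_r": -0.22, ...}
```

Read: every simulated patient had at least one lesion detected at low field,
but the smallest lesion the low-field arm recovers averages ~6 mm versus
~2.6 mm at high field — resolution, not contrast, is the limiting factor —
while total lesion volume stays highly correlated between arms, with the
negative difference-versus-mean correlation indicating relative
over-segmentation of small lesion burdens at low field. Similarly,

```bash
python analysis/04_superres_averaging.py
```

shows a 3 × 4 × 2.5 mm lesion that is invisible in any single low-field
acquisition becoming detectable after ~3 repositioned acquisitions are
registered and averaged, with mean conspicuity rising monotonically in the
number of averages.

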