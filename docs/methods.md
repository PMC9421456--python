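# Methods

## The problem being modelled

Paired brain MRI of the same patient at high field (3T-class, 1 mm isotropic
T2-FLAIR) and portable low field (64 mT-class, 1.6 × 1.6 × 5 mm T2-FLAIR)
differs in three ways that matter for white-matter-lesion work: the voxel is
~12.8× larger at low field, the signal-to-noise per unit volume is lower, and
the image is blurrier. This package simulates that pairing with known lesion
ground truth and runs the comparison statistics a paired patient study would
use. Everything is synthetic; the value of the package is that every
evaluation statistic can be checked against the truth that generated the
data.

## Phantom

The head is geometric: a brain ellipsoid (default semi-axes 48 × 56 × 44 mm,
~0.5 L — a deliberately scaled-down brain that keeps the default grids at
112 × 128 × 104 voxels of 1 mm) surrounded by a 6 mm rim standing in for
cortex/scalp signal, two ellipsoidal ventricles, and ellipsoidal lesions.
Tissue means are in arbitrary units per modality (FLAIR: CSF 0.15, GM 0.85,
WM 1.0); a lesion is parameterized by its target conspicuity c, giving
μ_L = μ_WM (1+c)/(1−c), hyperintense on FLAIR/T2w and hypointense on T1w.
Voxels are classified by a centre-of-voxel test; normal-appearing WM (NAWM)
is white matter ≥ 3 mm from any lesion or ventricle.

White matter carries a multiplicative texture field (Gaussian random field,
4 % fractional SD, 0.8 mm correlation length, seeded per phantom). This is a
deliberate departure from perfectly piecewise-constant tissue: White-Stripe
style normalization z-scores intensities by the width of the WM intensity
distribution, and on constant tissue that width is an artifact of noise
alone, which makes any z threshold physically meaningless. The texture sets
the NAWM coefficient of variation to a realistic few percent and gives the
z-scale its meaning. Setting `texture_sd=0` restores exactly
piecewise-constant truth images (used by several tests).

## Acquisition forward model

An acquisition renders a truth volume through, in order:

1. **Rigid repositioning** — rotation/translation drawn uniformly within the
   preset bounds from the acquisition seed (patients do not sit in the same
   pose in two scanners).
2. **PSF blur** — Gaussian, FWHM per preset; the through-slice component can
   be set separately (`psf_fwhm_slice_mm`), because the dominant z-response
   of a 2D multislice acquisition is the slice profile itself, which is
   modelled by the next step, not by an extra Gaussian.
3. **Partial-volume sampling** — fine voxels are block-averaged into each
   scanner voxel (mass-preserving; this is what super-resolution averaging
   later exploits).
4. **Bias field** — multiplicative, a random polynomial of order 2 scaled to
   a preset maximum fractional deviation.
5. **Rician noise** — magnitude of two Gaussian quadrature channels of equal
   σ, optionally averaged over `n_averages` independent draws; Gaussian
   noise is available as a config option. In signal-free air this reduces to
   a Rayleigh distribution with SD 0.655 σ, which the tests verify.
6. **Reconstruction filter** — optional in-plane Gaussian applied to the
   magnitude image. Low-field product reconstructions apodize heavily; the
   practical consequence modelled here is that low-field noise is spatially
   correlated, not white at the voxel scale. Without this the variance of
   the Laplacian (a second-derivative statistic) is dominated by white noise
   rather than by edge sharpness and stops being a focus measure.

Presets: `3t_flair` (1 mm iso, PSF 0.8 mm, σ 0.02, 5 % bias),
`64mt_flair` (1.6 × 1.6 × 5 mm, PSF 3 mm, σ 0.12 with a 2.5 mm
reconstruction filter — effective air noise SD ≈ 0.05 in WM units — 10 %
bias), orthogonal sagittal/coronal variants, and `64mt_flair_sr`
(1.8 × 1.8 × 5 mm, σ 0.10, no reconstruction filter, sharp 0.5 mm slice
profile) for the repeated-acquisition protocol, which trades more
undersampling noise for shorter scans. Noise levels were chosen to put
white-matter SNR around 50 at high field and around 20 at low field,
ordinary values for these sequence classes.

## Preprocessing stand-ins

The pipeline contracts mirror what a real study would do with external
tools; each stand-in is validated against phantom truth and accepts real
tool output as drop-in files at the same interface.

- **Registration** is a contract, not an algorithm of this package: the
  SimpleITK registration framework (mean-squares or Mattes metric,
  multi-resolution regular-step gradient descent, seeded 25 % sampling)
  recovers known rigid perturbations within 0.5° / 0.5 mm on phantoms.
  Resampling is done in-package (linear for intensities, nearest for
  labels/masks, everywhere).
- **Bias correction** fits a low-order polynomial to log intensity in two
  stages: a global fit removes the bulk field, then the fit is repeated on
  voxels in the WM intensity band of the *corrected* image (mode ± 3
  histogram-peak widths). The band must be selected after the first pass: on
  a strongly biased image an intensity band is an iso-bias shell, not a
  tissue. The two stages keep ventricles and the rim from masquerading as
  bias (a bias-free image passes through essentially unchanged) while still
  recovering a 20 %-amplitude field to well under 5 % residual.
- **Brain masking**: Otsu threshold, largest component, morphological
  closing, hole filling. Dice ≥ 0.98 against truth brain on phantoms.
- **White-Stripe normalization**: the WM mode is the last prominent peak of
  the smoothed in-mask histogram; the ±0.05-quantile "stripe" around it
  supplies the centre. The scale is estimated from the curvature of the
  histogram peak (Gaussian fit to log-counts near the mode) rather than the
  SD of the stripe itself: a narrow quantile slice measures its own width,
  not the tissue SD, and the downstream z thresholds assume NAWM has roughly
  unit variance.

## Stand-in segmenter

Real studies use a trained multimodal probability-map producer; here the
map is logistic((z_s − z_cut)/s) inside the brain mask, with z_cut = 1.5,
s = 0.1, where z_s is the White-Stripe z-map smoothed with a 2-voxel-FWHM
in-mask Gaussian. The smoothing stands in for the spatial regularization a
trained model provides: an unsmoothed unit-variance z-map thresholded near
1.4 σ fires on ~8 % of pure-noise voxels at any field strength, since
z-scoring removes the noise level from the decision. `smooth_fwhm_vox=0`
restores the literal unsmoothed behaviour. Maps are thresholded at p ≥ 0.2
(boundary inclusive) and components under 3 voxels discarded (the despeckle
floor is configurable and documented as an addition — upstream pipelines
rarely state one).

Because the smoothing kernel is defined in voxels, it is a 2 mm kernel at
high field but a 3.2 × 3.2 × 10 mm kernel at low field; together with the
12.8× voxel and the 3 mm PSF this is what makes sub-5 mm lesions invisible
at low field while the high-field arm sees them — the central asymmetry the
cohort statistics quantify.

## Cohort design

Each simulated patient draws 5–9 lesions with log-uniform diameters
2–12 mm, plus 1–4 large lesions (10–20 mm) and one guaranteed punctate
lesion (2–2.8 mm). The guaranteed components reflect an MS population with
established disease (every patient has a confluent-scale lesion and
punctate foci) and anchor the two tails the analysis measures: total lesion
volume spans roughly 1–15 ml across patients, and the smallest-lesion
statistic is defined in every study. Lesion conspicuity is drawn uniformly
in 0.18–0.32 on FLAIR. Placement rejects overlap with ventricles and other
lesions.

Per study: both arms are rendered from one anatomy (independent
repositioning, bias and noise), each arm is masked, bias-corrected,
normalized and segmented; truth-referenced detection uses the *known*
repositioning transform to carry per-lesion truth labels onto each
acquisition grid (evaluation may use ground truth; estimation may not);
the paired-field comparison estimates the high-field→low-field rigid
registration and evaluates on the low-field grid (nearest-neighbour mask
resampling). Bland–Altman differences are low-field minus high-field, so
over-segmentation at low field appears positive; the SEM is SD(d)/√2 by
default (configurable to SD(d), the formula being convention-dependent).

## Super-resolution experiments

Iterative averaging: each acquisition is resliced to the target isotropic
grid, affine-registered to the *first* acquisition (a register-to-evolving-
average mode exists behind a flag), and a running mean is formed; a
motion-corrupted acquisition whose registration fails is skipped with a
warning. Orthogonal fusion reslices axial/sagittal/coronal acquisitions to
a common isotropic grid, registers the latter two to the axial scan and
averages.

The sub-slice-lesion experiment constructs the hard case: a 3 × 4 × 2.5 mm
(~0.03 ml, conspicuity 0.38) lesion centred exactly between the slice
centres of the first acquisition, so the first scan samples the worst slice
phase. Subsequent repositioned acquisitions sample other phases, so the
running mean recovers partial-volume signal while the noise floor falls as
√N; the lesion crosses the stand-in segmentation threshold at N ≈ 3 and the
conspicuity curve rises toward its asymptote. Conspicuity is measured on a
fixed truth-derived ROI pair defined on the first acquisition's resliced
grid. Because the lesion ROI holds only ~10 voxels, single-run curves are
shot-noise limited; trend statements are made on the mean curve over 5
seeded replicates, and the monotonicity check is statistical (no step may
decrease by more than twice its replicate standard error).

The √N noise-reduction check through this pipeline uses nearest-neighbour
interpolation: linear interpolation attenuates voxel-wise noise by its
weights, which would mix an interpolation factor into the averaging law
being verified. The air ROI for noise measurements keeps 10 mm clear of the
head (beyond the repositioning bounds) and of the grid border (where
resampling pads).

## Numerical conventions

- RAS world frame, axis-aligned affines, 0-based indices, centre-of-voxel
  sampling; spacing is defined as the affine's column norms so the two can
  never disagree.
- Probability threshold is inclusive (p ≥ t). Connected components default
  to 26-connectivity (6 and 18 available); labels are ordered by first
  voxel in scan order so tables are deterministic.
- Dmax adds one in-plane voxel pitch (the larger of the two in-plane
  spacings) to the centre-to-centre span, so a single voxel has a nonzero
  diameter; the maximum is taken over all three orthogonal plane families.
  The manual-rater convention of measuring confluent periventricular
  lesions perpendicular to the ventricle is not emulated.
- Degenerate cases are defined and flagged rather than raised where a
  cohort can hit them: Dice of two empty masks is 1 (flagged), FDR with no
  predicted lesions is NaN (flagged), sweep rows with empty filtered sets
  are flagged, not dropped.
- ICC(2,1) is computed from the two-way ANOVA mean squares with the
  Shrout–Fleiss F-based 95 % interval; pingouin's implementation is used as
  an independent cross-check in the test suite only.
- All randomness flows from explicit integer seeds; a study seed spawns
  per-acquisition substreams, and identical (config, seed) reruns are
  bit-identical.

## What the synthetic data does and does not show

The phantom reproduces the mechanisms that drive the paired-field
comparison — partial volume, noise floors, blur, bias, repositioning — but
not real anatomy: no gyral folding, no periventricular confluence, no
vascular or artifactual false-positive sources (flow-related hyperintense
veins, peripheral artifacts), and the stand-in segmenter has none of the
failure modes of a trained model. Passing tests therefore demonstrate that
the *measurement machinery* is correct and that the expected physics
(resolution-limited small-lesion detection, √N averaging, focus loss under
blur) emerges from it — not that a particular scanner or segmentation model
attains any particular clinical sensitivity. Absolute Dice and FDR values
in the simulation are more favourable than on real patient data, where
registration error, anatomy and artifacts dominate; the direction and
ordering of effects, not their absolute levels, are the meaningful outputs.

Problem sizes (0.5 L brain, 20-study cohorts, 5 super-resolution
replicates) are the package defaults chosen to keep a full analysis run in
minutes on a laptop core; all are configurable upward.
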