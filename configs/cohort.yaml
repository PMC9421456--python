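# Default paired-field cohort configuration (see lowfield.cohort.StudyConfig).
# Run with:  lowfield cohort --config configs/cohort.yaml --out results/cohort
n_studies: 20
seed: 1
highfield_preset: 3t_flair
lowfield_preset: 64mt_flair

# lesion population per simulated patient
n_lesions_min: 5
n_lesions_max: 9
n_large_min: 1
n_large_max: 4
diameter_min_mm: 2.0
diameter_max_mm: 12.0
large_diameter_min_mm: 10.0
large_diameter_max_mm: 20.0
punctate_diameter_max_mm: 2.8
contrast_min: 0.18
contrast_max: 0.32

# stand-in segmentation
prob_threshold: 0.2
z_cut: 1.5
logistic_scale: 0.1
smooth_fwhm_vox: 2.0
min_voxels: 3

# evaluation
connectivity: 26
size_thresholds: [0.0, 0.25, 0.5, 1.0, 1.5, 2.5]
intensity_thresholds: [0.0, 2.0, 4.0, 8.0]
outdir: results/cohort
make_plots: false
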