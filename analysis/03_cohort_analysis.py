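#!/usr/bin/env python
"""Run the full simulated paired-field cohort.

Twenty studies with known lesion ground truth are rendered at the high- and
low-field presets, segmented with the stand-in pipeline, and evaluated:
total-volume recovery and agreement (Pearson, Bland-Altman), Dice between
field strengths, lesion-wise TPR/FDR sweeps by size and intensity, and the
smallest/largest detected lesion diameter per field.  Writes
results/cohort/ (studies.csv, tpr_fdr_sweeps.csv, aggregate.json, plots).
"""
import json
import warnings

from lowfield.cohort import StudyConfig, run_cohort, write_cohort_report

SEED = 1
N_STUDIES = 20


def main() -> None:
    warnings.filterwarnings("ignore")
    cfg = StudyConfig(n_studies=N_STUDIES, seed=SEED, outdir="results/cohort", make_plots=True)
    result = run_cohort(cfg)
    outdir = write_cohort_report(result, cfg)
    agg = result["aggregate"]
    print(json.dumps(agg, indent=2, default=float))
    print(
        f"\nacross {agg['n_studies']} studies the smallest detected lesion averaged "
        f"{agg['mean_smallest_detected_dmax_lf_mm']:.1f} mm at low field versus "
        f"{agg['mean_smallest_detected_dmax_hf_mm']:.1f} mm at high field, while "
        f"total lesion volume remained highly correlated between fields "
        f"(r = {agg['hf_vs_lf_agreement']['pearson_r']:.2f})."
    )
    print(f"report written to {outdir}")


if __name__ == "__main__":
    main()
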