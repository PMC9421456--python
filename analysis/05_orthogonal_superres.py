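#!/usr/bin/env python
"""Orthogonal-plane super-resolution fusion.

Axial, sagittal and coronal low-field FLAIR acquisitions (5 mm slices in
three orthogonal directions) of one anatomy are resliced to 1.6 mm isotropic,
registered to the axial scan and averaged.  Reports lesion conspicuity for
each single acquisition and for the fused volume under linear and
nearest-neighbour interpolation.  Writes results/orthogonal_sr.csv.
"""
import warnings

import numpy as np
import pandas as pd

from lowfield.harmonize import resample_to_grid, reslice
from lowfield.phantom import (
    PRESETS,
    LesionSpec,
    PhantomSpec,
    _rigid_world_matrix,
    build_phantom,
    simulate_acquisition,
    spawn_seeds,
)
from lowfield.quality import RoiSet, conspicuity
from lowfield.superres import orthogonal_sr

SEED = 9


def main() -> None:
    warnings.filterwarnings("ignore")
    spec = PhantomSpec(
        lesions=[
            LesionSpec(center=(18.0, 6.0, 18.0), semi_axes=(2.5, 3.0, 2.5), contrast={"FLAIR": 0.25, "T1w": -0.15})
        ],
        texture_seed=SEED,
    )
    truth = build_phantom(spec)
    seeds = spawn_seeds(SEED, 3)
    acqs = {
        "axial": simulate_acquisition(truth.images["FLAIR"], PRESETS["64mt_flair"], seeds[0]),
        "sagittal": simulate_acquisition(truth.images["FLAIR"], PRESETS["64mt_flair_sagittal"], seeds[1]),
        "coronal": simulate_acquisition(truth.images["FLAIR"], PRESETS["64mt_flair_coronal"], seeds[2]),
    }

    def truth_rois(vol, source):
        # carry the truth masks through the source acquisition's known
        # repositioning (the fused volume lives in the axial scan's frame)
        meta = source.meta["acquisition"]
        world = _rigid_world_matrix(meta["reposition_angles_deg"], meta["reposition_trans_mm"])
        t = np.linalg.inv(world)
        lesion = resample_to_grid(
            truth.lesion_mask, vol.affine, vol.shape, interp="nearest", world_transform=t
        ).data.astype(bool)
        nawm = resample_to_grid(
            truth.nawm_mask, vol.affine, vol.shape, interp="nearest", world_transform=t
        ).data.astype(bool)
        return RoiSet(lesion=lesion, nawm=nawm & ~lesion)

    rows = []
    for name, acq in acqs.items():
        iso = reslice(acq, (1.6, 1.6, 1.6))
        rows.append({"volume": name, "conspicuity": conspicuity(iso, truth_rois(iso, acq))})
    for interp in ("linear", "nearest"):
        fused = orthogonal_sr(acqs["axial"], acqs["sagittal"], acqs["coronal"], 1.6, interp=interp)
        rows.append(
            {
                "volume": f"superres_{interp}",
                "conspicuity": conspicuity(fused, truth_rois(fused, acqs["axial"])),
            }
        )

    df = pd.DataFrame(rows)
    df.to_csv("results/orthogonal_sr.csv", index=False)
    print(df.round(4).to_string(index=False))
    print("\nfused volume is 1.6 mm isotropic, enabling multi-planar review in one")
    print("volume with conspicuity comparable to the individual acquisitions.")
    print("wrote results/orthogonal_sr.csv")


if __name__ == "__main__":
    main()
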