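"""Phantom construction and the acquisition forward model."""
import numpy as np
import pytest

from lowfield import (
    AcquisitionSpec,
    LesionSpec,
    PhantomSpec,
    build_phantom,
    simulate_acquisition,
    simulate_paired_study,
)
from lowfield.phantom import PRESETS
from lowfield.quality import RoiSet, snr


def lesion_count_oracle(spec, lesion):
    """Brute-force centre-of-voxel membership count over the whole grid."""
    from lowfield.image import centered_affine

    aff = centered_affine(spec.grid_shape, spec.fine_spacing)
    count = 0
    cx, cy, cz = lesion.center
    ax, ay, az = lesion.semi_axes
    for i in range(spec.grid_shape[0]):
        x = aff[0, 0] * i + aff[0, 3]
        if abs(x - cx) > ax:
            continue
        for j in range(spec.grid_shape[1]):
            y = aff[1, 1] * j + aff[1, 3]
            if abs(y - cy) > ay:
                continue
            for k in range(spec.grid_shape[2]):
                z = aff[2, 2] * k + aff[2, 3]
                if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1:
                    count += 1
    return count


class TestBuildPhantom:
    def test_no_lesions_gives_empty_mask(self):
        truth = build_phantom(PhantomSpec())
        assert truth.lesion_mask.data.sum() == 0
        assert len(truth.lesion_table) == 0

    def test_sphere_voxel_count_matches_bruteforce_and_analytic(self):
        # centre aligned with a voxel centre so lattice counting is benign
        les = LesionSpec(center=(25.5, -20.5, 10.5), semi_axes=(5, 5, 5))
        spec = PhantomSpec(lesions=[les])
        truth = build_phantom(spec)
        n = int(truth.lesion_mask.data.sum())
        assert n == lesion_count_oracle(spec, les)
        analytic = 4.0 / 3.0 * np.pi * 5**3
        assert abs(n / analytic - 1) < 0.02

    def test_contrast_fraction_inverts_to_intensity(self, flat_truth):
        # conspicuity 0.25 on WM=1.0 -> lesion intensity (1+c)/(1-c)
        les = flat_truth.lesion_mask.data.astype(bool)
        vals = np.unique(flat_truth.images["FLAIR"].data[les])
        assert vals.shape == (1,)
        assert vals[0] == pytest.approx(1.25 / 0.75, abs=1e-12)

    def test_contrast_02_gives_15(self):
        spec = PhantomSpec(
            texture_sd=0.0,
            lesions=[LesionSpec(center=(25.5, -20.5, 10.5), semi_axes=(5, 5, 5), contrast={"FLAIR": 0.2, "T1w": -0.1})],
        )
        truth = build_phantom(spec)
        les = truth.lesion_mask.data.astype(bool)
        assert np.unique(truth.images["FLAIR"].data[les])[0] == pytest.approx(1.5, abs=1e-12)

    def test_lesion_outside_brain_names_index(self):
        with pytest.raises(ValueError, match="lesion 1"):
            PhantomSpec(
                lesions=[
                    LesionSpec(center=(0, -30, 0), semi_axes=(3, 3, 3)),
                    LesionSpec(center=(100, 0, 0), semi_axes=(3, 3, 3)),
                ]
            )

    def test_lesion_in_ventricle_rejected(self):
        spec = PhantomSpec(lesions=[LesionSpec(center=(11, 6, 8), semi_axes=(3, 3, 3))])
        with pytest.raises(ValueError, match="ventricle"):
            build_phantom(spec)

    def test_wrong_sign_contrast_rejected(self):
        with pytest.raises(ValueError, match="hyperintense"):
            PhantomSpec(lesions=[LesionSpec(center=(20, 0, 0), semi_axes=(3, 3, 3), contrast={"FLAIR": -0.2})])

    def test_masks_disjoint_and_consistent(self, default_truth):
        les = default_truth.lesion_mask.data.astype(bool)
        nawm = default_truth.nawm_mask.data.astype(bool)
        air = default_truth.air_mask.data.astype(bool)
        assert not np.any(les & nawm)
        assert not np.any(les & air)
        assert not np.any(nawm & air)
        # NAWM margin: no NAWM voxel within 3 mm of a lesion
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~les)
        assert dist[nawm].min() >= 3.0

    def test_nominal_volume_and_dmax(self):
        les = LesionSpec(center=(0, 0, 0), semi_axes=(1.5, 2.0, 2.5))
        assert les.nominal_volume_ml == pytest.approx(4 / 3 * np.pi * 1.5 * 2 * 2.5 / 1000)
        assert les.nominal_dmax_mm == 5.0


class TestSimulateAcquisition:
    def test_identity_pipeline_is_exact(self, flat_truth):
        acq = AcquisitionSpec(target_spacing=(1, 1, 1))
        out = simulate_acquisition(flat_truth.images["FLAIR"], acq, seed=1)
        assert np.array_equal(out.data, flat_truth.images["FLAIR"].data)

    def test_same_seed_bit_identical(self, default_truth):
        acq = PRESETS["64mt_flair"]
        a = simulate_acquisition(default_truth.images["FLAIR"], acq, seed=9)
        b = simulate_acquisition(default_truth.images["FLAIR"], acq, seed=9)
        assert np.array_equal(a.data, b.data)
        c = simulate_acquisition(default_truth.images["FLAIR"], acq, seed=10)
        assert not np.array_equal(a.data, c.data)

    def test_target_finer_than_grid_rejected(self, default_truth):
        acq = AcquisitionSpec(target_spacing=(0.5, 1, 1))
        with pytest.raises(ValueError, match="finer"):
            simulate_acquisition(default_truth.images["FLAIR"], acq, seed=0)

    def test_air_noise_is_rayleigh(self, default_truth):
        # signal-free magnitude noise: SD/sigma -> sqrt((4-pi)/2)
        acq = AcquisitionSpec(target_spacing=(1, 1, 1), noise_sigma=0.05)
        out = simulate_acquisition(default_truth.images["FLAIR"], acq, seed=3)
        air = default_truth.air_mask.data.astype(bool)
        assert air.sum() >= 1e5
        ratio = out.data[air].std(ddof=1) / 0.05
        assert ratio == pytest.approx(np.sqrt((4 - np.pi) / 2), rel=0.03)

    def test_partial_volume_preserves_mass(self, flat_truth):
        # divisible geometry: block averaging preserves the global mean
        acq = AcquisitionSpec(target_spacing=(2.0, 2.0, 4.0))
        out = simulate_acquisition(flat_truth.images["FLAIR"], acq, seed=0)
        fine = flat_truth.images["FLAIR"].data.mean()
        assert out.data.mean() == pytest.approx(fine, rel=0.005)

    def test_gaussian_noise_option(self, flat_truth):
        acq = AcquisitionSpec(target_spacing=(1, 1, 1), noise_sigma=0.05, noise_model="gaussian")
        out = simulate_acquisition(flat_truth.images["FLAIR"], acq, seed=3)
        air = flat_truth.air_mask.data.astype(bool)
        # Gaussian air noise keeps zero mean, unlike the Rician magnitude floor
        assert abs(out.data[air].mean()) < 0.001

    def test_averaging_raises_snr_sqrt_n(self, default_truth):
        rois = RoiSet(
            lesion=default_truth.lesion_mask.data,
            nawm=default_truth.nawm_mask.data,
            air=default_truth.air_mask.data,
        )
        img = default_truth.images["FLAIR"]
        snrs = {}
        for n in (1, 2, 4):
            acq = AcquisitionSpec(target_spacing=(1, 1, 1), noise_sigma=0.05, n_averages=n)
            snrs[n] = snr(simulate_acquisition(img, acq, seed=11), rois)
        assert snrs[2] / snrs[1] == pytest.approx(np.sqrt(2), rel=0.10)
        assert snrs[4] / snrs[1] == pytest.approx(2.0, rel=0.10)


class TestPairedStudy:
    def test_voxel_volume_ratio_about_13(self):
        hf = PRESETS["3t_flair"]
        lf = PRESETS["64mt_flair"]
        ratio = np.prod(lf.target_spacing) / np.prod(hf.target_spacing)
        assert ratio == pytest.approx(12.8)
        assert round(ratio) == 13

    def test_truth_table_bookkeeping(self):
        rng = np.random.default_rng(0)
        lesions = []
        # 20 lesions, diameters 2-16 mm, placed on a coarse grid of safe spots
        centers = [(x, y, z) for x in (-28, -14, 0, 14, 28) for y in (-36, -20) for z in (-20, 20)]
        for i, c in enumerate(centers):
            d = 2 + 14 * i / 19
            lesions.append(LesionSpec(center=c, semi_axes=(d / 2,) * 3))
        spec = PhantomSpec(lesions=lesions)
        study = simulate_paired_study(spec, PRESETS["3t_flair"], PRESETS["64mt_flair"], seed=5)
        assert len(study.truth.lesion_table) == 20
        assert (study.truth.lesion_table["volume_ml"] > 0).all()
        assert study.provenance["phantom"]["n_lesions"] == 20

    def test_seed_changes_noise_not_truth(self):
        spec = PhantomSpec(lesions=[LesionSpec(center=(25.5, -20.5, 10.5), semi_axes=(4, 4, 4))])
        a = simulate_paired_study(spec, PRESETS["3t_flair"], PRESETS["64mt_flair"], seed=1)
        b = simulate_paired_study(spec, PRESETS["3t_flair"], PRESETS["64mt_flair"], seed=2)
        assert np.array_equal(a.truth.lesion_mask.data, b.truth.lesion_mask.data)
        assert not np.array_equal(a.lowfield["FLAIR"].data, b.lowfield["FLAIR"].data)
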