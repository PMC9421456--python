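"""Digital brain phantom with ground-truth lesions and paired-field acquisition rendering.

The phantom is deliberately geometric (ellipsoidal brain with a thin cortical
rim and two ventricles) so the repository needs no atlas download.  White-matter
lesions are ellipsoids placed in the white matter, T2-FLAIR/T2w hyperintense and
T1w hypointense.  An acquisition renders the continuous truth through a forward
model: rigid repositioning, Gaussian point-spread blur, multiplicative bias
field, partial-volume block averaging onto the scanner grid, and Rician
magnitude noise (optionally averaged over repeated excitations).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VolumeImage, centered_affine

TISSUE_LABELS = {"air": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4}

#: Arbitrary-unit tissue means per modality.  FLAIR suppresses CSF; lesions are
#: T1w-hypointense and T2w/FLAIR-hyperintense relative to WM.
DEFAULT_TISSUE_INTENSITIES = {
    "FLAIR": {"air": 0.0, "csf": 0.15, "gm": 0.85, "wm": 1.0},
    "T1w": {"air": 0.0, "csf": 0.20, "gm": 0.80, "wm": 1.0},
    "T2w": {"air": 0.0, "csf": 1.30, "gm": 0.90, "wm": 0.70},
}

DEFAULT_LESION_CONTRAST = {"FLAIR": 0.25, "T2w": 0.20, "T1w": -0.15}


@dataclass
class LesionSpec:
    """Ellipsoidal lesion: centre (mm, world), semi-axes (mm) and per-modality
    target conspicuity (mu_L - mu_WM)/(mu_L + mu_WM)."""

    center: tuple
    semi_axes: tuple
    contrast: dict = field(default_factory=lambda: dict(DEFAULT_LESION_CONTRAST))

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        self.semi_axes = tuple(float(s) for s in self.semi_axes)
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("lesion semi-axes must be positive")
        for c in self.contrast.values():
            if not -1 < c < 1:
                raise ValueError("contrast fraction must lie in (-1, 1)")

    @property
    def nominal_volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    @property
    def nominal_dmax_mm(self) -> float:
        return 2.0 * max(self.semi_axes)

    def intensity(self, wm_intensity: float, modality: str) -> float:
        """Invert the conspicuity definition: mu_L = mu_WM (1+c)/(1-c)."""
        c = self.contrast.get(modality, 0.0)
        return wm_intensity * (1.0 + c) / (1.0 - c)


@dataclass
class PhantomSpec:
    """Continuous digital head: brain ellipsoid + cortical rim + ventricles + lesions."""

    grid_shape: tuple = (112, 128, 104)
    fine_spacing: tuple = (1.0, 1.0, 1.0)
    brain_semi_axes: tuple = (48.0, 56.0, 44.0)
    rim_thickness_mm: float = 6.0
    ventricles: tuple = (
        ((-11.0, 6.0, 8.0), (7.0, 18.0, 9.0)),
        ((11.0, 6.0, 8.0), (7.0, 18.0, 9.0)),
    )
    tissue_intensities: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TISSUE_INTENSITIES.items()}
    )
    lesions: list = field(default_factory=list)
    nawm_margin_mm: float = 3.0
    # multiplicative tissue texture: fractional SD and correlation length of a
    # smooth Gaussian random field shared across modalities (0 disables it and
    # makes the truth images exactly piecewise-constant)
    texture_sd: float = 0.04
    texture_corr_mm: float = 0.8
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.fine_spacing):
            raise ValueError("fine_spacing must be positive on all axes")
        for mod, table in self.tissue_intensities.items():
            if any(v < 0 for v in table.values()):
                raise ValueError(f"negative tissue intensity for {mod}")
        for i, les in enumerate(self.lesions):
            r = sum(
                (c / a) ** 2 for c, a in zip(les.center, self.brain_semi_axes)
            )
            if r > 1.0:
                raise ValueError(f"lesion {i} centre lies outside the brain ellipsoid")
            fl = les.contrast.get("FLAIR")
            if fl is not None and fl <= 0:
                raise ValueError(f"lesion {i} must be FLAIR-hyperintense (contrast > 0)")
            t1 = les.contrast.get("T1w")
            if t1 is not None and t1 >= 0:
                raise ValueError(f"lesion {i} must be T1w-hypointense (contrast < 0)")


@dataclass
class PhantomTruth:
    """Ground truth rendered on the fine grid."""

    images: dict  # modality -> VolumeImage (piecewise-constant truth)
    lesion_mask: VolumeImage
    lesion_labels: VolumeImage  # 0 = background, i+1 = lesion i
    tissue_labels: VolumeImage
    nawm_mask: VolumeImage
    air_mask: VolumeImage
    lesion_table: pd.DataFrame
    spec: PhantomSpec


def _inside_ellipsoid(axes_xyz, center, semi_axes):
    x, y, z = axes_xyz
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec, modalities=("FLAIR",)) -> PhantomTruth:
    """Rasterize the phantom: label map, truth intensities, and truth masks.

    Voxels are classified by a centre-of-voxel test.  NAWM is white matter at
    least ``nawm_margin_mm`` from any lesion and from the ventricle boundary.
    Air is everything outside the head-bounding ellipsoid (brain + rim).
    """
    affine = centered_affine(spec.grid_shape, spec.fine_spacing)
    ref = VolumeImage(np.zeros(spec.grid_shape), affine, modality="label")
    axes = ref.world_coords()

    head_axes = tuple(a + spec.rim_thickness_mm for a in spec.brain_semi_axes)
    head = _inside_ellipsoid(axes, (0, 0, 0), head_axes)
    brain = _inside_ellipsoid(axes, (0, 0, 0), spec.brain_semi_axes)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[head] = TISSUE_LABELS["gm"]  # rim stands in for cortex/scalp signal
    labels[brain] = TISSUE_LABELS["wm"]

    vent_mask = np.zeros(spec.grid_shape, dtype=bool)
    for center, semi in spec.ventricles:
        vent_mask |= _inside_ellipsoid(axes, center, semi)
    vent_mask &= brain
    labels[vent_mask] = TISSUE_LABELS["csf"]

    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    lesion_ids = np.zeros(spec.grid_shape, dtype=np.int16)
    per_lesion_masks = []
    rows = []
    for i, les in enumerate(spec.lesions):
        m = _inside_ellipsoid(axes, les.center, les.semi_axes) & brain
        if np.any(m & vent_mask):
            raise ValueError(f"lesion {i} overlaps a ventricle")
        per_lesion_masks.append(m)
        lesion_mask |= m
        lesion_ids[m] = i + 1
        rows.append(
            {
                "lesion_id": i,
                "center_x_mm": les.center[0],
                "center_y_mm": les.center[1],
                "center_z_mm": les.center[2],
                "volume_ml": les.nominal_volume_ml,
                "dmax_mm": les.nominal_dmax_mm,
                "voxel_count": int(m.sum()),
                **{f"contrast_{m_}": c for m_, c in les.contrast.items()},
            }
        )
    labels[lesion_mask] = TISSUE_LABELS["lesion"]

    # NAWM: WM >= margin from lesions and from the ventricle boundary
    wm = labels == TISSUE_LABELS["wm"]
    excl = lesion_mask | vent_mask
    if np.any(excl):
        dist = ndimage.distance_transform_edt(~excl, sampling=spec.fine_spacing)
    else:
        dist = np.full(spec.grid_shape, np.inf)
    nawm = wm & (dist >= spec.nawm_margin_mm)

    # smooth multiplicative tissue texture (sets the in-tissue intensity SD
    # that White-Stripe normalization sees; real NAWM is not perfectly flat)
    if spec.texture_sd > 0:
        trng = np.random.default_rng(spec.texture_seed)
        raw = trng.standard_normal(spec.grid_shape)
        sigma_vox = spec.texture_corr_mm / np.asarray(spec.fine_spacing)
        smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox)
        smooth /= max(smooth[head].std(), 1e-12)
        texture = 1.0 + spec.texture_sd * smooth
    else:
        texture = None

    images = {}
    for mod in modalities:
        table = spec.tissue_intensities[mod]
        lut = np.array(
            [table["air"], table["csf"], table["gm"], table["wm"], table["wm"]]
        )
        img = lut[labels]
        for les, m in zip(spec.lesions, per_lesion_masks):
            img[m] = les.intensity(table["wm"], mod)
        if texture is not None:
            img = np.where(labels > 0, img * texture, img)
        images[mod] = VolumeImage(np.clip(img.astype(float), 0, None), affine, modality=mod)

    mk = lambda arr, tag: VolumeImage(arr.astype(np.uint8), affine, modality=tag)
    return PhantomTruth(
        images=images,
        lesion_mask=mk(lesion_mask, "mask"),
        lesion_labels=VolumeImage(lesion_ids, affine, modality="label"),
        tissue_labels=VolumeImage(labels.astype(np.int16), affine, modality="label"),
        nawm_mask=mk(nawm, "mask"),
        air_mask=mk(~head, "mask"),
        lesion_table=pd.DataFrame(rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Acquisition forward model
# ---------------------------------------------------------------------------

SLICE_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class AcquisitionSpec:
    """Field-strength preset: scanner grid and degradation model.

    ``noise_sigma`` is the Gaussian sigma of the two quadrature channels
    whose magnitude forms the Rician sample; ``n_averages`` averages
    independent noise draws of identical geometry.
    """

    target_spacing: tuple = (1.0, 1.0, 1.0)
    slice_axis: str = "axial"
    psf_fwhm_mm: float = 0.0
    #: PSF FWHM along the slice axis; None keeps the PSF isotropic.  The box
    #: average over the slice thickness is modelled separately by the
    #: partial-volume downsampling, so a small value here means "sharp slice
    #: profile" rather than "no through-plane blur".
    psf_fwhm_slice_mm: float | None = None
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    bias_order: int = 2
    reposition_max_rot_deg: float = 0.0
    reposition_max_trans_mm: float = 0.0
    n_averages: int = 1
    noise_model: str = "rician"  # or "gaussian"
    #: in-plane FWHM (mm) of a post-noise reconstruction filter (k-space
    #: apodization smooths the magnitude image and correlates its noise;
    #: 0 disables it)
    recon_filter_fwhm_mm: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.slice_axis not in SLICE_AXIS_INDEX:
            raise ValueError(f"unknown slice_axis {self.slice_axis!r}")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")


#: Acquisition geometry presets mirroring the study's sequence table: 1 mm
#: isotropic FLAIR at high field vs 1.6x1.6x5 mm at 64 mT (the low-field
#: voxel is 12.8x larger), and the 1.8x1.8x5 mm repeated-acquisition variant
#: used for iterative super-resolution averaging.
PRESETS = {
    "3t_flair": AcquisitionSpec(
        target_spacing=(1.0, 1.0, 1.0),
        slice_axis="axial",
        psf_fwhm_mm=0.8,
        noise_sigma=0.02,
        bias_amplitude=0.05,
        reposition_max_rot_deg=2.0,
        reposition_max_trans_mm=2.0,
        name="3t_flair",
    ),
    "64mt_flair": AcquisitionSpec(
        target_spacing=(1.6, 1.6, 5.0),
        slice_axis="axial",
        psf_fwhm_mm=3.0,
        noise_sigma=0.12,
        bias_amplitude=0.10,
        reposition_max_rot_deg=4.0,
        reposition_max_trans_mm=4.0,
        recon_filter_fwhm_mm=2.5,
        name="64mt_flair",
    ),
    "64mt_flair_sagittal": AcquisitionSpec(
        target_spacing=(5.0, 1.6, 1.6),
        slice_axis="sagittal",
        psf_fwhm_mm=3.0,
        noise_sigma=0.12,
        bias_amplitude=0.10,
        reposition_max_rot_deg=4.0,
        reposition_max_trans_mm=4.0,
        recon_filter_fwhm_mm=2.5,
        name="64mt_flair_sagittal",
    ),
    "64mt_flair_coronal": AcquisitionSpec(
        target_spacing=(1.6, 5.0, 1.6),
        slice_axis="coronal",
        psf_fwhm_mm=3.0,
        noise_sigma=0.12,
        bias_amplitude=0.10,
        reposition_max_rot_deg=4.0,
        reposition_max_trans_mm=4.0,
        recon_filter_fwhm_mm=2.5,
        name="64mt_flair_coronal",
    ),
    # repeated-acquisition super-resolution protocol: slightly coarser in-plane,
    # more undersampling (noisier), repositioning between scans
    "64mt_flair_sr": AcquisitionSpec(
        target_spacing=(1.8, 1.8, 5.0),
        slice_axis="axial",
        psf_fwhm_mm=3.0,
        psf_fwhm_slice_mm=0.5,
        noise_sigma=0.10,
        bias_amplitude=0.05,
        reposition_max_rot_deg=3.0,
        reposition_max_trans_mm=4.0,
        name="64mt_flair_sr",
    ),
}


def _rigid_world_matrix(angles_deg, trans_mm) -> np.ndarray:
    """World-to-world rigid map: rotate about the origin (volume centre), then translate."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    mat = np.eye(4)
    mat[:3, :3] = rz @ ry @ rx
    mat[:3, 3] = np.asarray(trans_mm, dtype=float)
    return mat


def _apply_rigid(truth: VolumeImage, world_mat: np.ndarray) -> np.ndarray:
    """Resample truth under a world rigid motion (output on the same fine grid)."""
    if np.allclose(world_mat, np.eye(4), atol=1e-12):
        return np.asarray(truth.data, dtype=float)
    # output(v) = truth(A^-1 @ M^-1 @ A @ v)
    a = truth.affine
    vox_mat = np.linalg.inv(a) @ np.linalg.inv(world_mat) @ a
    return ndimage.affine_transform(
        np.asarray(truth.data, dtype=float),
        vox_mat[:3, :3],
        offset=vox_mat[:3, 3],
        order=1,
        mode="constant",
        cval=0.0,
    )


def _coarse_grid(truth: VolumeImage, target_spacing) -> tuple:
    """Coarse grid covering the fine field of view, centred within it."""
    fine_spacing = truth.spacing
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target < fine_spacing - 1e-9):
        raise ValueError("target spacing finer than the fine grid")
    shape = np.asarray(truth.shape)
    fov = shape * fine_spacing
    n = np.maximum(1, np.floor(fov / target + 1e-9).astype(int))
    # world position of the outer edge of fine voxel 0
    origin_edge = truth.affine[:3, 3] - fine_spacing / 2.0
    offset = (fov - n * target) / 2.0
    origin_center = origin_edge + offset + target / 2.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(target)
    affine[:3, 3] = origin_center
    return tuple(n), affine, origin_edge + offset


def _block_average(data: np.ndarray, truth: VolumeImage, n, coarse_edge, target) -> np.ndarray:
    """Partial-volume model: average fine voxels whose centres fall in each coarse voxel."""
    idx = []
    for ax in range(3):
        centers = truth.affine[ax, 3] + np.arange(truth.shape[ax]) * truth.spacing[ax]
        k = np.floor((centers - coarse_edge[ax]) / target[ax]).astype(int)
        idx.append(k)
    ii = idx[0][:, None, None]
    jj = idx[1][None, :, None]
    kk = idx[2][None, None, :]
    valid = (
        (ii >= 0) & (ii < n[0]) & (jj >= 0) & (jj < n[1]) & (kk >= 0) & (kk < n[2])
    )
    flat = (ii * n[1] + jj) * n[2] + kk
    flat = np.where(valid, flat, 0).ravel()
    w = valid.ravel().astype(float)
    sums = np.bincount(flat, weights=data.ravel() * w, minlength=int(np.prod(n)))
    counts = np.bincount(flat, weights=w, minlength=int(np.prod(n)))
    counts[counts == 0] = 1.0
    return (sums / counts).reshape(n)


def _bias_field(shape, affine, amplitude, order, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * p(u)/max|p|, p a random polynomial."""
    if amplitude == 0:
        return np.ones(shape)
    ref = VolumeImage(np.zeros(shape), affine, modality="label")
    axes = ref.world_coords()
    half = [max(abs(float(a.min())), abs(float(a.max())), 1e-9) for a in axes]
    u = [a / h for a, h in zip(axes, half)]
    f = np.zeros(shape)
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                if px + py + pz == 0:
                    continue
                f = f + rng.normal() * (u[0] ** px) * (u[1] ** py) * (u[2] ** pz)
    peak = np.max(np.abs(f))
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * f / peak


def simulate_acquisition(truth: VolumeImage, acq: AcquisitionSpec, seed: int) -> VolumeImage:
    """Render one scan: rigid reposition, PSF blur, partial-volume downsample,
    bias field, Rician noise averaged over ``n_averages`` draws.

    Deterministic given (truth, acq, seed).
    """
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-acq.reposition_max_rot_deg, acq.reposition_max_rot_deg, 3)
    trans = rng.uniform(-acq.reposition_max_trans_mm, acq.reposition_max_trans_mm, 3)
    world_mat = _rigid_world_matrix(angles, trans)

    data = _apply_rigid(truth, world_mat)
    if acq.psf_fwhm_mm > 0 or (acq.psf_fwhm_slice_mm or 0) > 0:
        fwhm = np.full(3, float(acq.psf_fwhm_mm))
        if acq.psf_fwhm_slice_mm is not None:
            fwhm[SLICE_AXIS_INDEX[acq.slice_axis]] = acq.psf_fwhm_slice_mm
        sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / truth.spacing
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)

    n, affine, coarse_edge = _coarse_grid(truth, acq.target_spacing)
    target = np.asarray(acq.target_spacing, dtype=float)
    if tuple(n) == truth.shape and np.allclose(affine, truth.affine, atol=1e-9):
        coarse = data  # identity geometry: no resampling
    else:
        coarse = _block_average(data, truth, n, coarse_edge, target)

    bias = _bias_field(tuple(n), affine, acq.bias_amplitude, acq.bias_order, rng)
    signal = coarse * bias

    if acq.noise_sigma > 0:
        acc = np.zeros_like(signal)
        for _ in range(acq.n_averages):
            if acq.noise_model == "gaussian":
                acc += signal + rng.normal(0.0, acq.noise_sigma, signal.shape)
            else:
                n1 = rng.normal(0.0, acq.noise_sigma, signal.shape)
                n2 = rng.normal(0.0, acq.noise_sigma, signal.shape)
                acc += np.sqrt((signal + n1) ** 2 + n2**2)
        signal = acc / acq.n_averages

    if acq.recon_filter_fwhm_mm > 0:
        sigma_mm = acq.recon_filter_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_recon = sigma_mm / np.asarray(acq.target_spacing)
        sigma_recon[SLICE_AXIS_INDEX[acq.slice_axis]] = 0.0  # in-plane only
        signal = ndimage.gaussian_filter(signal, sigma=sigma_recon)

    out = VolumeImage(signal, affine, modality=truth.modality)
    out.meta["acquisition"] = {
        **asdict(acq),
        "seed": int(seed),
        "reposition_angles_deg": [float(a) for a in angles],
        "reposition_trans_mm": [float(t) for t in trans],
    }
    return out


@dataclass
class PairedStudy:
    """Two renderings of one anatomy (high-field and low-field) plus truth."""

    truth: PhantomTruth
    highfield: dict  # modality -> VolumeImage
    lowfield: dict
    provenance: dict

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mod, img in self.truth.images.items():
            img.save(outdir / f"truth_{mod}.nii.gz")
        self.truth.lesion_mask.save(outdir / "truth_lesion_mask.nii.gz")
        self.truth.tissue_labels.save(outdir / "truth_tissue_labels.nii.gz")
        self.truth.nawm_mask.save(outdir / "truth_nawm_mask.nii.gz")
        self.truth.air_mask.save(outdir / "truth_air_mask.nii.gz")
        self.truth.lesion_table.to_csv(outdir / "truth_lesions.csv", index=False)
        for tag, imgs in (("highfield", self.highfield), ("lowfield", self.lowfield)):
            for mod, img in imgs.items():
                img.save(outdir / f"{tag}_{mod}.nii.gz")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=float)
        return outdir


def spawn_seeds(seed: int, n: int) -> list:
    """Deterministic child seeds (< 2**31) from one study seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_paired_study(
    phantom: PhantomSpec,
    hf: AcquisitionSpec,
    lf: AcquisitionSpec,
    seed: int,
    modalities=("FLAIR",),
) -> PairedStudy:
    """Render the same anatomy on both scanners with independent noise/positioning."""
    truth = build_phantom(phantom, modalities=modalities)
    seeds = spawn_seeds(seed, 2 * len(modalities))
    highfield, lowfield = {}, {}
    prov_acq = {}
    for i, mod in enumerate(modalities):
        highfield[mod] = simulate_acquisition(truth.images[mod], hf, seeds[2 * i])
        lowfield[mod] = simulate_acquisition(truth.images[mod], lf, seeds[2 * i + 1])
        prov_acq[mod] = {
            "highfield": highfield[mod].meta["acquisition"],
            "lowfield": lowfield[mod].meta["acquisition"],
        }
    provenance = {
        "seed": int(seed),
        "phantom": {
            "grid_shape": list(phantom.grid_shape),
            "fine_spacing": list(phantom.fine_spacing),
            "brain_semi_axes": list(phantom.brain_semi_axes),
            "n_lesions": len(phantom.lesions),
        },
        "acquisitions": prov_acq,
    }
    return PairedStudy(truth=truth, highfield=highfield, lowfield=lowfield, provenance=provenance)
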