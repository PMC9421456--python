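"""Core 3D volume container and NIfTI round-trip.

All volumes in this package are axis-aligned grids in a RAS world frame with
0-based voxel indices and centre-of-voxel sampling: world = affine @ (i,j,k,1).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("T1w", "T2w", "FLAIR")


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing, world affine and modality tag.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity grid. Must be finite everywhere.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS) transform. Voxel spacing is the column norms of
        the 3x3 block, so spacing and affine can never disagree.
    modality : str
        One of ``T1w``, ``T2w``, ``FLAIR`` (or ``mask``/``label`` for
        non-intensity volumes).
    meta : dict
        Free-form provenance (normalization parameters, acquisition record).
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "FLAIR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray, modality: str | None = None) -> "VolumeImage":
        """New volume on this grid with different data."""
        return VolumeImage(
            data=np.asarray(data),
            affine=self.affine.copy(),
            modality=modality or self.modality,
            meta=dict(self.meta),
        )

    def world_coords(self, sparse: bool = True):
        """Open (broadcastable) world-coordinate axes for this grid."""
        axes = []
        for ax, n in enumerate(self.shape):
            idx = np.zeros((n, 3))
            idx[:, ax] = np.arange(n)
            w = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
            shape = [1, 1, 1]
            shape[ax] = n
            axes.append(w[:, ax].reshape(shape) if _is_axis_aligned(self.affine) else w)
        if not _is_axis_aligned(self.affine):
            raise NotImplementedError("world_coords requires an axis-aligned affine")
        return axes

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, modality: str = "FLAIR") -> "VolumeImage":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            affine=np.asarray(img.affine, dtype=float),
            modality=modality,
        )


def _is_axis_aligned(affine: np.ndarray, atol: float = 1e-9) -> bool:
    block = np.abs(affine[:3, :3])
    return bool(np.all(block - np.diag(np.diag(block)) < atol))


def centered_affine(shape, spacing) -> np.ndarray:
    """Axis-aligned RAS affine placing the grid centre at world origin."""
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing
    return affine


def as_bool_mask(vol: "VolumeImage | np.ndarray") -> np.ndarray:
    """Validate and return a boolean mask array from a volume or array."""
    data = vol.data if isinstance(vol, VolumeImage) else np.asarray(vol)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask is not binary (values other than 0/1 present)")
    return data.astype(bool)
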