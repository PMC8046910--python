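"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np


@dataclass
class BoldRun:
    """A 4D BOLD run: voxel grid (x, y, z, t) plus acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD values in arbitrary scanner units.
    tr_s : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; must be invertible.
    n_discarded : int
        Leading volumes already dropped from this run.
    provenance : {"rest", "task"}
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_discarded: int = 0
    provenance: str = "rest"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD run must contain at least one volume")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.provenance not in ("rest", "task"):
            raise ValueError("provenance must be 'rest' or 'task'")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)

    def to_nifti(self) -> nib.Nifti1Image:
        # float64 on disk so volumes round-trip without value change
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path, tr_s: float | None = None, provenance: str = "rest",
                   n_discarded: int = 0) -> "BoldRun":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(data=data, tr_s=float(tr_s), affine=np.asarray(img.affine),
                   n_discarded=n_discarded, provenance=provenance)


@dataclass
class MaskVolume:
    """Binary 3D mask aligned to a :class:`BoldRun` grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.n_voxels == 0:
            raise ValueError("mask is empty")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def coords(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates, C-order."""
        return np.argwhere(self.data)

    def contains(self, other: "MaskVolume") -> bool:
        return bool(np.all(self.data[other.data]))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "MaskVolume":
        img = nib.load(str(path))
        return cls(data=np.asanyarray(img.dataobj), affine=np.asarray(img.affine))
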