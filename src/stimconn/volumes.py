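"""Voxel-grid containers shared across the pipeline.

All volumes live on a common grid: a shape plus a 4x4 affine mapping
0-based voxel indices to world coordinates in millimetres. The reference
space of the analysis is a 1 mm isotropic grid, mirroring how normative
connectomes are projected for seed-based fibre filtering. Voxels are
half-open boxes centred on the affine image of their integer index, so a
world point belongs to voxel ``i`` iff ``round(voxel_coord) == i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "VAT", "GridMismatchError", "EmptyVATError", "resample_nearest"]


class GridMismatchError(ValueError):
    """Two volumes do not share shape/affine and cannot be combined."""


class EmptyVATError(ValueError):
    """An operation that normalizes by VAT volume received an empty VAT."""


@dataclass(frozen=True)
class Grid:
    """A voxel lattice: integer shape and voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def matches(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "Grid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what}: grids differ (shape {self.shape} vs {other.shape}, "
                "or affines disagree)"
            )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (Nvox, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T.astype(float)
        return self.voxel_to_world(idx)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Integer voxel index of the voxel containing each world point."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.ones(len(ijk), dtype=bool)
        for d in range(3):
            ok &= (ijk[:, d] >= 0) & (ijk[:, d] < self.shape[d])
        return ok

    def to_nifti(self, data: np.ndarray, descrip: str | None = None) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(data), self.affine)
        if descrip is not None:
            img.header["descrip"] = descrip.encode()[:79]
        return img

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Grid":
        return cls(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def resample_nearest(data: np.ndarray, source: Grid, target: Grid) -> np.ndarray:
    """Nearest-neighbour resampling of a label/mask volume onto another
    grid. The reference analysis path assumes one shared standard space;
    resampling is a convenience for mismatched inputs and warns, since
    nearest-neighbour assignment shifts region boundaries by up to half
    a voxel."""
    import warnings

    if source.matches(target):
        return np.asarray(data)
    warnings.warn(
        "resampling between grids (nearest neighbour): boundaries may shift "
        "by up to half a voxel; prefer a single shared space"
    )
    centers = target.voxel_centers()
    ijk = np.rint(source.world_to_voxel(centers)).astype(int)
    inside = source.inside(ijk)
    out = np.zeros(int(np.prod(target.shape)), dtype=np.asarray(data).dtype)
    ijk = np.clip(ijk, 0, np.asarray(source.shape) - 1)
    vals = np.asarray(data)[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    out[inside] = vals[inside]
    return out.reshape(target.shape)


@dataclass
class VAT:
    """Volume of activated tissue: a binary mask on the analysis grid.

    The seed object for every downstream step — atlas overlap, fibre
    selection and voxel-wise density mapping all start from this mask.
    """

    mask: np.ndarray
    grid: Grid
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridMismatchError("VAT mask shape does not match its grid")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def union(self, other: "VAT") -> "VAT":
        self.grid.require_match(other.grid, "VAT union")
        return VAT(self.mask | other.mask, self.grid, hemisphere="bilateral")

    def to_nifti(self, descrip: str | None = None) -> nib.Nifti1Image:
        return self.grid.to_nifti(self.mask.astype(np.uint8), descrip)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, hemisphere: str = "") -> "VAT":
        data = np.asarray(img.dataobj) > 0.5
        return cls(mask=data, grid=Grid.from_nifti(img), hemisphere=hemisphere)
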