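"""Streamline-level connectivity seeded from stimulation volumes.

A streamline "touches" a mask iff, after resampling the polyline to an
arc-length step no coarser than 0.5 mm, any sample point falls inside a
mask voxel. Resampling prevents tunnelling: a fibre whose raw vertices
straddle a one-voxel-thick mask still registers as connected. Fibre
counts are raw streamline counts, unweighted by length or density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import VAT, Grid

__all__ = [
    "Tractogram",
    "resample_streamline",
    "streamlines_touching",
    "fiber_count_to_roi",
    "voxel_fiber_density",
    "bilateral_seed",
    "DEFAULT_RESAMPLE_STEP",
]

DEFAULT_RESAMPLE_STEP = 0.5  # mm, < 1 mm voxel size


@dataclass
class Tractogram:
    """Ordered 3D point sequences in world mm with stable integer ids."""

    streamlines: list[np.ndarray]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline needs >= 2 points of shape (n, 3)")
            if not np.isfinite(s).all():
                raise ValueError("streamline coordinates must be finite")
        if self.ids is None:
            self.ids = np.arange(len(self.streamlines))
        self.ids = np.asarray(self.ids, dtype=int)
        if len(self.ids) != len(self.streamlines):
            raise ValueError("ids and streamlines length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("fibre ids must be unique")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return zip(self.ids, self.streamlines)

    def subset(self, keep_ids) -> "Tractogram":
        keep = set(int(i) for i in keep_ids)
        pairs = [(i, s) for i, s in self if int(i) in keep]
        if not pairs:
            return Tractogram(streamlines=[], ids=np.array([], dtype=int))
        ids, sls = zip(*pairs)
        return Tractogram(streamlines=list(sls), ids=np.asarray(ids))

    # -- I/O ------------------------------------------------------------
    def save_trk(self, path: str | Path, grid: Grid) -> None:
        """TRK with the grid's affine recorded in the header."""
        tg = nib.streamlines.Tractogram(
            self.streamlines, affine_to_rasmm=np.eye(4)
        )
        header = {
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "voxel_sizes": np.abs(np.diag(grid.affine)[:3]).astype(np.float32),
            "dimensions": np.asarray(grid.shape, dtype=np.int16),
        }
        nib.streamlines.save(tg, str(path), header=header)

    @classmethod
    def load(cls, path: str | Path) -> "Tractogram":
        """Load TRK/TCK (world mm, via nibabel) or the TSV fallback."""
        path = Path(path)
        if path.suffix == ".tsv":
            return cls.load_tsv(path)
        tf = nib.streamlines.load(str(path))
        return cls(streamlines=[np.asarray(s) for s in tf.streamlines])

    def save_tsv(self, path: str | Path) -> None:
        """Plain-text fallback: columns fiber_id, x, y, z; points in order."""
        with open(path, "w") as fh:
            fh.write("fiber_id\tx\ty\tz\n")
            for fid, s in self:
                for p in s:
                    fh.write(f"{fid}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Tractogram":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        ids, sls = [], []
        for fid, g in df.groupby("fiber_id", sort=True):
            ids.append(int(fid))
            sls.append(g[["x", "y", "z"]].to_numpy())
        return cls(streamlines=sls, ids=np.asarray(ids, dtype=int))


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc length <= ``step`` mm,
    keeping both endpoints."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    length = float(seg.sum())
    if length == 0.0:
        return points[:1]
    n = max(int(np.ceil(length / step)), 1)
    t_old = np.concatenate([[0.0], np.cumsum(seg)])
    t_new = np.linspace(0.0, length, n + 1)
    return np.column_stack(
        [np.interp(t_new, t_old, points[:, d]) for d in range(3)]
    )


def _touch_mask(
    mask: np.ndarray, grid: Grid, tractogram: Tractogram, step: float
) -> np.ndarray:
    """Boolean per-fibre: does any resampled point land in a mask voxel?"""
    out = np.zeros(len(tractogram), dtype=bool)
    for k, (_, s) in enumerate(tractogram):
        pts = resample_streamline(s, step)
        ijk = grid.world_to_index(pts)
        ok = grid.inside(ijk)
        if not ok.any():
            continue
        ijk = ijk[ok]
        out[k] = bool(mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any())
    return out


def streamlines_touching(
    vat: VAT, tractogram: Tractogram, step: float = DEFAULT_RESAMPLE_STEP
) -> set[int]:
    """Ids of fibres with at least one resampled point inside the VAT."""
    if len(tractogram) == 0:
        return set()
    hit = _touch_mask(vat.mask, vat.grid, tractogram, step)
    return set(int(i) for i in tractogram.ids[hit])


def fiber_count_to_roi(
    vat: VAT,
    roi_mask: np.ndarray,
    tractogram: Tractogram,
    step: float = DEFAULT_RESAMPLE_STEP,
) -> int:
    """Count of streamlines touching BOTH the VAT seed and the ROI."""
    if len(tractogram) == 0:
        return 0
    hit_vat = _touch_mask(vat.mask, vat.grid, tractogram, step)
    hit_roi = _touch_mask(np.asarray(roi_mask, dtype=bool), vat.grid, tractogram, step)
    return int((hit_vat & hit_roi).sum())


def voxel_fiber_density(
    vat: VAT,
    tractogram: Tractogram,
    grid: Grid | None = None,
    step: float = DEFAULT_RESAMPLE_STEP,
) -> np.ndarray:
    """Per-voxel count of VAT-connected fibres passing through the voxel.

    Each fibre contributes at most 1 per voxel regardless of how many of
    its points fall there.
    """
    grid = grid or vat.grid
    vat.grid.require_match(grid, "density grid")
    density = np.zeros(grid.shape, dtype=np.int32)
    if len(tractogram) == 0:
        return density
    hit = _touch_mask(vat.mask, vat.grid, tractogram, step)
    for k, (_, s) in enumerate(tractogram):
        if not hit[k]:
            continue
        ijk = grid.world_to_index(resample_streamline(s, step))
        ijk = ijk[grid.inside(ijk)]
        if len(ijk) == 0:
            continue
        uniq = np.unique(ijk, axis=0)
        density[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return density


def bilateral_seed(vat_left: VAT, vat_right: VAT) -> VAT:
    """Voxelwise union of the hemispheric VATs: the seed used for all
    whole-brain connectivity operations."""
    return vat_left.union(vat_right)
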