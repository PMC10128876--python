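"""Atlas handling and VAT-subregion overlap metrics.

The STN is parcellated into a dorsolateral *motor* subregion and a
ventromedial *non-motor* subregion (associative and limbic territories,
reported combined for all headline statistics). Overlap of a stimulation
volume with a subregion is expressed as the fraction of VAT voxels inside
that subregion, and hemispheric fractions are averaged per subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import VAT, EmptyVATError, Grid

__all__ = [
    "Parcellation",
    "normalized_intersection",
    "bilateral_average",
    "outside_stn_fraction",
    "overlap_report",
]

HEMISPHERES = ("left", "right")
# Combined for headline statistics; kept separate in the label map.
NONMOTOR_PARTS = ("associative", "limbic")


@dataclass
class Parcellation:
    """Labelled voxel volume with a name -> integer-code label map.

    STN subregion labels follow the pattern ``stn_<part>_<hemi>`` with
    part in {motor, associative, limbic}; 0 is background. Labels are
    mutually exclusive by construction (one code per voxel).
    """

    data: np.ndarray
    grid: Grid
    labels: dict[str, int]
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError("parcellation shape does not match grid")
        for name, mask in self.roi_masks.items():
            if mask.shape != self.grid.shape:
                raise ValueError(f"ROI mask {name!r} shape does not match grid")

    def mask_for(self, names: str | list[str]) -> np.ndarray:
        """Boolean mask of the union of the named labels."""
        if isinstance(names, str):
            names = [names]
        codes = [self.labels[n] for n in names]
        return np.isin(self.data, codes)

    def stn_labels(self, hemisphere: str, parts: tuple[str, ...] | None = None) -> list[str]:
        parts = parts or ("motor", *NONMOTOR_PARTS)
        return [f"stn_{p}_{hemisphere}" for p in parts if f"stn_{p}_{hemisphere}" in self.labels]

    # -- I/O ------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """NIfTI label volume + JSON label-map sidecar (+ ROI NIfTIs)."""
        path = Path(path)
        nib.save(self.grid.to_nifti(self.data.astype(np.int16)), path)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        with open(str(sidecar) + "_labels.json", "w") as fh:
            json.dump(self.labels, fh, indent=1, sort_keys=True)
        for name, mask in self.roi_masks.items():
            nib.save(
                self.grid.to_nifti(mask.astype(np.uint8)),
                path.parent / f"roi_{name}.nii.gz",
            )

    @classmethod
    def load(cls, path: str | Path) -> "Parcellation":
        path = Path(path)
        img = nib.load(path)
        sidecar = path.with_suffix("").with_suffix("")
        with open(str(sidecar) + "_labels.json") as fh:
            labels = {k: int(v) for k, v in json.load(fh).items()}
        roi_masks = {}
        for roi_path in sorted(path.parent.glob("roi_*.nii.gz")):
            name = roi_path.name[len("roi_") : -len(".nii.gz")]
            roi_masks[name] = np.asarray(nib.load(roi_path).dataobj) > 0.5
        return cls(
            data=np.asarray(img.dataobj).astype(int),
            grid=Grid.from_nifti(img),
            labels=labels,
            roi_masks=roi_masks,
        )


def _check_vat(vat: VAT, parcellation: Parcellation) -> None:
    parcellation.grid.require_match(vat.grid, "VAT vs parcellation")
    if vat.is_empty:
        raise EmptyVATError(
            "overlap fraction is undefined for an empty VAT "
            "(normalization divides by VAT volume)"
        )


def normalized_intersection(
    vat: VAT, parcellation: Parcellation, region: str | list[str]
) -> float:
    """|VAT ∩ region| / |VAT| by voxel counts.

    ``region`` may be a single label name or a list whose union is taken
    (e.g. associative + limbic = non-motor).
    """
    _check_vat(vat, parcellation)
    region_mask = parcellation.mask_for(region)
    return float((vat.mask & region_mask).sum()) / vat.n_voxels


def outside_stn_fraction(vat: VAT, parcellation: Parcellation, hemisphere: str) -> float:
    """Fraction of the VAT outside the (whole) STN of one hemisphere:
    the complement of motor + non-motor, closing the partition exactly."""
    labels = parcellation.stn_labels(hemisphere)
    return 1.0 - normalized_intersection(vat, parcellation, labels)


def bilateral_average(left_fraction: float, right_fraction: float) -> float:
    """Arithmetic mean of the hemispheric fractions; a missing hemisphere
    (NaN/None) propagates as NaN with a warning."""
    vals = [left_fraction, right_fraction]
    vals = [np.nan if v is None else float(v) for v in vals]
    if any(np.isnan(v) for v in vals):
        warnings.warn("one hemisphere missing: bilateral overlap is undefined")
        return float("nan")
    return float(np.mean(vals))


def overlap_report(
    vats: dict[str, dict[str, VAT]], parcellation: Parcellation
) -> pd.DataFrame:
    """Per-subject normalized intersections with the STN subregions.

    ``vats`` maps subject id -> {hemisphere -> VAT}. Returns one row per
    subject with hemispheric and bilaterally averaged motor, non-motor
    and outside-STN fractions.
    """
    rows = []
    for subject, per_hemi in vats.items():
        row: dict[str, float | str] = {"subject": subject}
        for metric in ("motor", "nonmotor", "outside"):
            per_side = {}
            for hemi in HEMISPHERES:
                vat = per_hemi.get(hemi)
                if vat is None:
                    per_side[hemi] = np.nan
                    continue
                if metric == "motor":
                    val = normalized_intersection(vat, parcellation, f"stn_motor_{hemi}")
                elif metric == "nonmotor":
                    labels = parcellation.stn_labels(hemi, NONMOTOR_PARTS)
                    val = normalized_intersection(vat, parcellation, labels)
                else:
                    val = outside_stn_fraction(vat, parcellation, hemi)
                per_side[hemi] = val
                row[f"{metric}_{hemi}"] = val
            row[metric] = bilateral_average(per_side["left"], per_side["right"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")
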