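"""Directional DBS lead geometry, simplified electric-field model and VAT.

The lead modelled here is an 8-contact directional electrode: a ring
contact at the distal and at the proximal pole and, in between, two rows
of three segments spaced 120 degrees apart, which allows the stimulation
volume to be steered radially.

The electric field is a homogeneous-medium point-source superposition:
each active contact contributes ``E(r) = k * I_c / r**2`` (V/mm), with
``I_c`` the current apportioned to that contact (mA) and ``k`` a medium
constant (V*mm/mA, configurable). This deliberately replaces a
finite-element tissue model while preserving the properties downstream
analysis relies on: a fixed activation threshold (0.2 V/mm), linear
scaling with amplitude, and directional steering by segment weighting.
``r`` is clamped below at the contact radius so the field stays finite on
the contact surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import VAT, Grid, GridMismatchError

__all__ = [
    "LeadModel",
    "StimSettings",
    "EFieldGrid",
    "contact_positions",
    "efield",
    "vat_from_efield",
    "DEFAULT_VAT_THRESHOLD",
    "DEFAULT_FIELD_CONSTANT",
]

# Activation threshold on the E-field magnitude, V/mm.
DEFAULT_VAT_THRESHOLD = 0.2
# Homogeneous-medium constant, V*mm/mA: a ~2 mA ring program yields a VAT
# radius of ~2.4 mm, the scale typically reported for therapeutic programs.
DEFAULT_FIELD_CONSTANT = 0.6


@dataclass
class LeadModel:
    """Geometry of one implanted directional lead in world mm."""

    tip: np.ndarray
    axis: np.ndarray
    rotation_deg: float = 0.0
    # Distance from tip to the centre of the distal ring contact.
    tip_offset: float = 1.5
    # Centre-to-centre spacing between contact rows (1.5 mm contacts,
    # 0.5 mm gaps on the modelled lead).
    row_spacing: float = 2.0
    lead_radius: float = 0.65

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise ValueError("lead axis must be a non-zero vector")
        self.axis = axis / norm

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2) perpendicular to the axis; e1 is the
        zero-rotation reference direction."""
        ref = np.zeros(3)
        ref[int(np.argmin(np.abs(self.axis)))] = 1.0
        e1 = np.cross(self.axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.axis, e1)
        return e1, e2


# (row, angular slot) layout of the 8 contacts, distal to proximal.
# Rows 0 and 3 are full rings (slot None); rows 1 and 2 carry three
# segments each at 120 degree spacing.
_CONTACT_LAYOUT: list[tuple[int, int | None]] = [
    (0, None),
    (1, 0),
    (1, 1),
    (1, 2),
    (2, 0),
    (2, 1),
    (2, 2),
    (3, None),
]


def contact_positions(lead: LeadModel) -> list[dict]:
    """Centroids and orientation of the 8 contacts, distal to proximal.

    Ring-contact centroids lie on the lead axis; segment centroids sit on
    the lead surface at 120 degree spacing, rotated by the lead's rotation
    about its axis.
    """
    e1, e2 = lead.frame()
    rot = np.deg2rad(lead.rotation_deg)
    contacts = []
    for index, (row, slot) in enumerate(_CONTACT_LAYOUT):
        along = lead.tip + (lead.tip_offset + row * lead.row_spacing) * lead.axis
        if slot is None:
            centroid = along
            direction = None
        else:
            theta = rot + slot * 2.0 * np.pi / 3.0
            direction = np.cos(theta) * e1 + np.sin(theta) * e2
            centroid = along + lead.lead_radius * direction
        contacts.append(
            {
                "index": index + 1,  # 1..8, distal ring first
                "row": row,
                "kind": "ring" if slot is None else "segment",
                "centroid": centroid,
                "direction": direction,
            }
        )
    return contacts


@dataclass
class StimSettings:
    """One hemisphere's stimulation program.

    ``shares`` maps contact index (1..8) to its fraction of the total
    current; active shares must sum to 1 when the amplitude is positive.
    Monopolar cathodic stimulation is assumed (the case handled by the
    activation-threshold heuristic).
    """

    amplitude_ma: float
    shares: dict[int, float] = field(default_factory=dict)
    hemisphere: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_ma < 0:
            raise ValueError("amplitude must be >= 0 mA")
        for c, s in self.shares.items():
            if not 1 <= int(c) <= 8:
                raise ValueError(f"contact index {c} outside 1..8")
            if s < 0:
                raise ValueError("current shares must be >= 0")
        total = sum(self.shares.values())
        if self.amplitude_ma > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError(f"active current shares sum to {total:.4f}, expected 1")

    @property
    def active_contacts(self) -> list[int]:
        return sorted(c for c, s in self.shares.items() if s > 0)


@dataclass
class EFieldGrid:
    """Scalar electric-field magnitude (V/mm) on the analysis grid."""

    data: np.ndarray
    grid: Grid
    active_positions: np.ndarray  # (n_active, 3) world mm, for CC selection

    def __post_init__(self) -> None:
        if self.data.shape != self.grid.shape:
            raise GridMismatchError("E-field data shape does not match grid")


def efield(
    settings: StimSettings,
    lead: LeadModel,
    grid: Grid,
    k: float = DEFAULT_FIELD_CONSTANT,
) -> EFieldGrid:
    """Point-source superposition field of all active contacts.

    Distances are clamped below at the lead radius, so the maximum
    attainable field for one contact is ``k * I_c / lead_radius**2``.
    """
    contacts = {c["index"]: c for c in contact_positions(lead)}
    centers = grid.voxel_centers()
    total = np.zeros(len(centers))
    active_pos = []
    for c_index, share in settings.shares.items():
        if share <= 0:
            continue
        pos = contacts[c_index]["centroid"]
        active_pos.append(pos)
        current = settings.amplitude_ma * share
        r = np.linalg.norm(centers - pos, axis=1)
        np.maximum(r, lead.lead_radius, out=r)
        total += k * current / (r * r)
    data = total.reshape(grid.shape)
    if not active_pos:
        active_pos = [lead.tip]
    return EFieldGrid(data=data, grid=grid, active_positions=np.asarray(active_pos))


def vat_from_efield(
    field: EFieldGrid,
    threshold: float = DEFAULT_VAT_THRESHOLD,
    hemisphere: str = "",
) -> VAT:
    """Threshold the field at ``threshold`` V/mm and keep the connected
    component(s) containing the active contacts.

    An empty mask (amplitude too low for any voxel to cross threshold) is
    a valid result and returns an empty VAT.
    """
    mask = field.data >= threshold
    if mask.any():
        labels, n = ndimage.label(mask)
        idx = field.grid.world_to_index(field.active_positions)
        keep: set[int] = set()
        for ijk in idx:
            ijk = np.clip(ijk, 0, np.asarray(field.grid.shape) - 1)
            lab = labels[tuple(ijk)]
            if lab > 0:
                keep.add(int(lab))
        if keep:
            mask = np.isin(labels, sorted(keep))
    return VAT(mask=mask, grid=field.grid, hemisphere=hemisphere)
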