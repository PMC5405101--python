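"""Structure sets: named binary masks on a voxel grid.

Holds the segmented anatomy (targets, organs at risk) plus all derived
planning structures the wishlist refers to: the lungs with the gross tumor
carved out, isotropic cord expansions, dose-falloff shells around the PTV
and the "unspecified tissue" remainder.  Margin expansion is exact
Euclidean expansion of voxel centers (per-axis scaled for anisotropic
margins), so a brute-force distance oracle reproduces it voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

# roles a structure can play
ROLE_TARGET = "target"
ROLE_OAR = "oar"
ROLE_DERIVED = "derived"
ROLE_EXTERNAL = "external"

#: structures every phantom must provide before planning structures can be derived
BASE_STRUCTURES = (
    "patient",
    "gtv",
    "lungs",
    "heart",
    "esophagus",
    "spinal_cord",
    "plexus",
)


class GeometryError(ValueError):
    """Raised for inconsistent structure geometry (e.g. tumor outside patient)."""


@dataclass
class StructureSet:
    """Named binary voxel masks sharing one grid.

    Invariants: every mask has the grid's shape; a ``patient`` mask exists
    and contains every other structure; ``ptv ⊇ ctv ⊇ gtv`` once targets
    are present.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, role: str = ROLE_DERIVED) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} has shape {mask.shape}, grid is {self.grid.shape}"
            )
        self.masks[name] = mask
        self.roles[name] = role

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not in set; available: {sorted(self.masks)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self.masks)

    def voxel_count(self, name: str) -> int:
        return int(self[name].sum())

    def volume_cc(self, name: str) -> float:
        return self.voxel_count(name) * self.grid.voxel_volume_mm3 / 1000.0

    def indices(self, name: str) -> np.ndarray:
        """Flat (C-order) voxel indices of a structure."""
        return np.flatnonzero(self[name].ravel())

    def centroid_mm(self, name: str) -> np.ndarray:
        """Center of mass of a mask in physical coordinates."""
        mask = self[name]
        if not mask.any():
            raise GeometryError(f"structure {name!r} is empty")
        idx = np.argwhere(mask)
        return np.asarray(self.grid.origin) + (idx.mean(axis=0) + 0.5) * np.asarray(
            self.grid.spacing
        )

    def validate(self) -> None:
        """Check the containment invariants; raise GeometryError on violation."""
        if "patient" not in self.masks:
            raise GeometryError("structure set lacks a 'patient' mask")
        patient = self.masks["patient"]
        for name, mask in self.masks.items():
            if name == "patient":
                continue
            if np.any(mask & ~patient):
                raise GeometryError(f"structure {name!r} extends outside the patient")
        chain = [n for n in ("ptv", "ctv", "gtv") if n in self.masks]
        for outer, inner in zip(chain, chain[1:]):
            if np.any(self.masks[inner] & ~self.masks[outer]):
                raise GeometryError(f"{inner!r} is not contained in {outer!r}")


def _as_margin_triple(margins: float | Iterable[float]) -> tuple[float, float, float]:
    if np.isscalar(margins):
        m = (float(margins),) * 3
    else:
        m = tuple(float(v) for v in margins)  # type: ignore[arg-type]
        if len(m) != 3:
            raise ValueError("margins must be a scalar or a length-3 sequence (mm per axis)")
    if any(v < 0 for v in m):
        raise ValueError(f"margins must be >= 0, got {m}")
    return m  # type: ignore[return-value]


def expand_margin(
    mask: np.ndarray, margins: float | Iterable[float], grid: VoxelGrid
) -> np.ndarray:
    """Expand a binary mask by a physical margin.

    A voxel joins the expanded mask when its center lies within the
    (per-axis scaled) Euclidean margin of some voxel center of the input:
    ``sqrt(sum_a (delta_a / m_a)^2) <= 1`` with ``delta_a`` the center
    offset in mm along axis ``a``.  Isotropic margins give a digital ball;
    anisotropic margins an ellipsoid.  A zero margin on some axis forbids
    growth along that axis.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    m = _as_margin_triple(margins)
    if not mask.any() or all(v == 0 for v in m):
        return mask.copy()
    # scaled-coordinate EDT: distance 1.0 marks the margin surface
    big = 1e9  # effectively blocks expansion along zero-margin axes
    sampling = [grid.spacing[a] / m[a] if m[a] > 0 else big for a in range(3)]
    dist = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return dist <= 1.0 + 1e-9


def derive_planning_structures(ss: StructureSet) -> StructureSet:
    """Add every derived mask the NSCLC wishlist refers to.

    Derived set (all plain boolean algebra on the stored masks):

    - ``lungs_minus_gtv``   = lungs \\ GTV
    - ``cord_plus_3mm``, ``cord_plus_5mm`` = isotropic cord expansions
    - ``ptv_minus_cord5``   = PTV \\ (cord + 5 mm)
    - ``shell_ptv_1cm``, ``shell_ptv_3cm`` = (PTV + d) \\ PTV, d = 10 / 30 mm
    - ``patient_minus_ptv4``= patient \\ (PTV + 4 cm)
    - ``unspecified_tissue``= patient minus the union of all named structures

    Modifies ``ss`` in place and returns it.
    """
    required = list(BASE_STRUCTURES) + ["ctv", "ptv"]
    missing = [n for n in required if n not in ss]
    if missing:
        raise GeometryError(f"cannot derive planning structures; missing: {missing}")

    g = ss.grid
    patient = ss["patient"]

    ss.add("lungs_minus_gtv", ss["lungs"] & ~ss["gtv"])
    cord3 = expand_margin(ss["spinal_cord"], 3.0, g) & patient
    cord5 = expand_margin(ss["spinal_cord"], 5.0, g) & patient
    ss.add("cord_plus_3mm", cord3)
    ss.add("cord_plus_5mm", cord5)
    ss.add("ptv_minus_cord5", ss["ptv"] & ~cord5)
    ptv = ss["ptv"]
    for name, d in (("shell_ptv_1cm", 10.0), ("shell_ptv_3cm", 30.0)):
        ss.add(name, expand_margin(ptv, d, g) & ~ptv & patient)
    ss.add("patient_minus_ptv4", patient & ~expand_margin(ptv, 40.0, g))
    named = np.zeros(g.shape, dtype=bool)
    for name in ("gtv", "ctv", "ptv", "lungs", "heart", "esophagus", "spinal_cord", "plexus"):
        named |= ss[name]
    ss.add("unspecified_tissue", patient & ~named)
    return ss


def cord_close_to_target(ss: StructureSet) -> bool:
    """Whether the expanded spinal cord touches or overlaps the PTV.

    "Close to the target" is operationalized as a nonempty intersection of
    (cord + 5 mm) with the PTV.
    """
    return bool(np.any(ss["cord_plus_5mm"] & ss["ptv"]))
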