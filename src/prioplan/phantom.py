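"""Synthetic voxelized thorax phantoms.

Generates a simplified axial thorax — elliptical patient contour, two
lung ellipses, heart, esophagus, spinal cord and brachial plexus — with a
spherical gross tumor volume (GTV) placed in one lung.  Target volumes
follow the clinical margin recipe: CTV = GTV + 5 mm, PTV = CTV + 10 mm
laterally / ventro-dorsally and 10–12 mm cranio-caudally.  A seeded cohort
generator varies tumor size and location so paired planning studies run on
reproducible pseudo-patients.

The phantom is a stand-in for segmented patient CT anatomy: geometry is
deliberately schematic, density is water-equivalent with a reduced scalar
density inside lung.  Coordinates are mm with the origin at the thorax
center; ``nz == 1`` grids give the fast planar mode used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .grid import VoxelGrid
from .structures import (
    GeometryError,
    ROLE_EXTERNAL,
    ROLE_OAR,
    ROLE_TARGET,
    StructureSet,
    derive_planning_structures,
    expand_margin,
)

#: default reduced density inside lung tissue (relative to water)
DEFAULT_LUNG_DENSITY = 0.26


@dataclass
class PhantomConfig:
    """Parameters for one synthetic thorax phantom.

    All lengths in mm.  ``tumor_center`` is relative to the thorax center;
    ``laterality`` mirrors the tumor/plexus to the left when ``"left"``.
    The same config and seed always produce bit-identical masks.
    """

    shape: tuple[int, int, int] = (40, 34, 1)
    spacing: tuple[float, float, float] = (6.0, 6.0, 6.0)
    # patient (thorax) ellipse semi-axes
    thorax_semi_axes: tuple[float, float] = (110.0, 85.0)
    # lung ellipses: lateral center offset and semi-axes
    lung_center_offset: tuple[float, float] = (48.0, 0.0)
    lung_semi_axes: tuple[float, float] = (42.0, 64.0)
    heart_center: tuple[float, float] = (-20.0, 14.0)
    heart_radius: float = 22.0
    esophagus_center: tuple[float, float] = (5.0, -36.0)
    esophagus_radius: float = 5.0
    cord_center: tuple[float, float] = (0.0, -62.0)
    cord_radius: float = 5.0
    plexus_center: tuple[float, float] = (78.0, 45.0)
    plexus_radius: float = 6.0
    tumor_center: tuple[float, float, float] = (56.0, 2.0, 0.0)
    tumor_radius: float = 9.0
    laterality: str = "right"
    ctv_margin_mm: float = 5.0
    ptv_margin_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    lung_density: float = DEFAULT_LUNG_DENSITY
    seed: int = 0
    # amplitude of seeded anatomical jitter applied to organ centers (mm)
    anatomy_jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.laterality not in ("right", "left"):
            raise ValueError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        if self.tumor_radius < 0:
            raise ValueError("tumor_radius must be >= 0")
        if not (0 < self.lung_density <= 1):
            raise ValueError("lung_density must be in (0, 1]")

    def grid(self) -> VoxelGrid:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        extent = [shape[a] * spacing[a] for a in range(3)]
        origin = tuple(-extent[a] / 2.0 for a in range(3))
        return VoxelGrid(shape, spacing, origin)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("shape", "spacing", "thorax_semi_axes", "lung_center_offset",
                    "lung_semi_axes", "heart_center", "esophagus_center", "cord_center",
                    "plexus_center", "tumor_center", "ptv_margin_mm"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)


def _ellipse(xy: np.ndarray, center: Sequence[float], semi: Sequence[float]) -> np.ndarray:
    u = (xy[..., 0] - center[0]) / semi[0]
    v = (xy[..., 1] - center[1]) / semi[1]
    return u * u + v * v <= 1.0


def _disk(xy: np.ndarray, center: Sequence[float], radius: float) -> np.ndarray:
    return _ellipse(xy, center, (radius, radius))


def build_phantom(config: PhantomConfig, derive: bool = True) -> StructureSet:
    """Build the structure set of one synthetic thorax phantom.

    Returns a :class:`StructureSet` with the base anatomy, the GTV/CTV/PTV
    chain and (unless ``derive=False``) every derived planning structure.
    Raises :class:`GeometryError` when the tumor is empty or pokes outside
    the patient contour.
    """
    grid = config.grid()
    rng = np.random.default_rng(config.seed)
    jit = config.anatomy_jitter_mm

    def jitter2() -> np.ndarray:
        # draw even when jitter is 0 to keep the stream layout stable
        return rng.uniform(-1.0, 1.0, size=2) * jit

    side = -1.0 if config.laterality == "left" else 1.0
    centers = grid.voxel_centers().reshape(grid.shape + (3,))
    xy = centers[..., :2]

    patient = _ellipse(xy, (0.0, 0.0), config.thorax_semi_axes)

    lox, loy = config.lung_center_offset
    lung_r = _ellipse(xy, np.array([+lox, loy]) + jitter2(), config.lung_semi_axes)
    lung_l = _ellipse(xy, np.array([-lox, loy]) + jitter2(), config.lung_semi_axes)
    heart = _disk(xy, np.array(config.heart_center) + jitter2(), config.heart_radius)
    esophagus = _disk(xy, np.array(config.esophagus_center) + jitter2(),
                      config.esophagus_radius)
    cord = _disk(xy, np.array(config.cord_center), config.cord_radius)
    plexus = _disk(xy, np.array([side * config.plexus_center[0], config.plexus_center[1]]),
                   config.plexus_radius)

    lungs = (lung_r | lung_l) & ~heart & ~esophagus & ~cord & ~plexus
    heart &= patient
    esophagus &= patient
    cord &= patient
    plexus &= patient
    lungs &= patient

    tc = np.array([side * abs(config.tumor_center[0]), config.tumor_center[1],
                   config.tumor_center[2]])
    d2 = ((centers - tc) ** 2).sum(axis=-1)
    gtv = d2 <= config.tumor_radius ** 2

    if not gtv.any():
        raise GeometryError(
            f"GTV is empty (radius {config.tumor_radius} mm on spacing {config.spacing})"
        )
    if np.any(gtv & ~patient):
        raise GeometryError("tumor extends outside the patient contour")

    ss = StructureSet(grid)
    ss.add("patient", patient, ROLE_EXTERNAL)
    ss.add("gtv", gtv, ROLE_TARGET)
    ss.add("lungs", lungs, ROLE_OAR)
    ss.add("heart", heart, ROLE_OAR)
    ss.add("esophagus", esophagus, ROLE_OAR)
    ss.add("spinal_cord", cord, ROLE_OAR)
    ss.add("plexus", plexus, ROLE_OAR)

    ctv = expand_margin(gtv, config.ctv_margin_mm, grid) & patient
    ptv = expand_margin(ctv, config.ptv_margin_mm, grid) & patient
    ss.add("ctv", ctv, ROLE_TARGET)
    ss.add("ptv", ptv, ROLE_TARGET)

    ss.validate()
    if derive:
        derive_planning_structures(ss)
    return ss
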