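"""Beamlet dose-influence computation and the fluence -> dose map.

A deliberately simple pencil-beam-like engine: each beamlet deposits

    dose(v, b) = exp(-mu * radiological_depth(v)) * exp(-lat(v, b)^2 / (2 sigma^2))

Gy per unit fluence at patient voxel ``v``, where the radiological depth
is the density-weighted path length from the patient surface to the voxel
along the (parallel) beam direction, and ``lat`` is the perpendicular
offset of the voxel from the beamlet axis.  Density is water-equivalent
(1.0) inside the patient and a reduced scalar inside lung tissue; voxels
outside the patient receive no dose.  Entries below a pruning threshold
(relative to each beamlet's maximum) are dropped to keep the matrix
sparse.  No scatter kernels, divergence or Monte Carlo — fidelity beyond
a smooth attenuated pencil is not the point of this engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .beams import BeamSet, beam_direction, lateral_direction
from .structures import StructureSet

__all__ = [
    "DoseInfluenceMatrix",
    "Plan",
    "density_map",
    "radiological_depth",
    "compute_dose_influence",
    "compute_dose",
]

DEFAULT_MU_PER_MM = 0.005
DEFAULT_SIGMA_MM = 3.0
DEFAULT_PRUNE_REL = 1e-4


@dataclass
class DoseInfluenceMatrix:
    """Sparse linear map from beamlet fluence to voxel dose (Gy per unit fluence).

    ``matrix`` is CSR with one row per grid voxel (C order) and one column
    per beamlet (beam-major order as in the beam set).
    """

    matrix: sparse.csr_matrix
    grid_shape: tuple[int, int, int]
    beamset: BeamSet

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def rows(self, mask: np.ndarray) -> sparse.csr_matrix:
        """Sub-matrix restricted to the voxels of a mask."""
        return self.matrix[np.flatnonzero(np.asarray(mask, bool).ravel())]


@dataclass
class Plan:
    """A fluence vector with its dose and provenance."""

    fluence: np.ndarray
    dose: np.ndarray
    prescription: object | None = None
    wishlist_name: str | None = None
    solver_log: list[dict] | None = None

    def __post_init__(self) -> None:
        self.fluence = np.asarray(self.fluence, float)
        self.dose = np.asarray(self.dose, float)
        if np.any(self.fluence < -1e-9):
            raise ValueError("plan fluence must be nonnegative")


def density_map(ss: StructureSet, lung_density: float = 0.26) -> np.ndarray:
    """Relative electron density: 1 in patient, ``lung_density`` in lung, 0 outside.

    The gross tumor is solid: GTV voxels keep density 1 even inside lung.
    """
    rho = np.zeros(ss.grid.shape)
    rho[ss["patient"]] = 1.0
    if "lungs" in ss:
        lung = ss["lungs"].copy()
        if "gtv" in ss:
            lung &= ~ss["gtv"]
        rho[lung] = lung_density
    return rho


def radiological_depth(
    ss: StructureSet,
    gantry_deg: float,
    density: np.ndarray,
    step_mm: float = 2.0,
) -> np.ndarray:
    """Density-weighted depth from the surface for every patient voxel.

    Marches from each voxel center back toward the source in ``step_mm``
    increments, sampling the density grid nearest-neighbor and summing
    ``rho * step`` until the ray leaves the grid.  Returns an array over
    the full grid (non-patient voxels hold inf).
    """
    grid = ss.grid
    patient = ss["patient"]
    u = beam_direction(gantry_deg)
    centers = grid.voxel_centers().reshape(grid.shape + (3,))[patient]

    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    extent = spacing * np.asarray(grid.shape)
    # longest chord through the grid bounds the march
    n_steps = int(np.ceil(np.linalg.norm(extent) / step_mm)) + 1

    depth = np.zeros(len(centers))
    for k in range(1, n_steps + 1):
        pos = centers - (k - 0.5) * step_mm * u
        idx = np.floor((pos - origin) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < grid.shape), axis=1)
        if not inside.any():
            break
        rho = np.zeros(len(centers))
        ii = idx[inside]
        rho[inside] = density[ii[:, 0], ii[:, 1], ii[:, 2]]
        depth += rho * step_mm

    out = np.full(grid.shape, np.inf)
    out[patient] = depth
    return out


def compute_dose_influence(
    ss: StructureSet,
    bs: BeamSet,
    mu_per_mm: float = DEFAULT_MU_PER_MM,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    lung_density: float = 0.26,
    prune_rel: float = DEFAULT_PRUNE_REL,
    depth_step_mm: float = 2.0,
) -> DoseInfluenceMatrix:
    """Assemble the sparse dose-influence matrix for a phantom and beam set.

    ``prune_rel = 0`` disables pruning (used by tests comparing against
    dense oracles).
    """
    if mu_per_mm <= 0:
        raise ValueError(f"attenuation mu must be > 0, got {mu_per_mm}")
    if sigma_mm <= 0:
        raise ValueError(f"lateral sigma must be > 0, got {sigma_mm}")
    grid = ss.grid
    patient = ss["patient"]
    pat_idx = np.flatnonzero(patient.ravel())
    centers = grid.voxel_centers()[pat_idx]
    rho = density_map(ss, lung_density)

    blocks = []
    for beam in bs.beams:
        depth = radiological_depth(ss, beam.gantry_deg, rho, depth_step_mm)
        att = np.exp(-mu_per_mm * depth.ravel()[pat_idx])
        lat = centers[:, :2] @ lateral_direction(beam.gantry_deg)[:2]
        z = centers[:, 2]
        bl_lat, bl_z = beam.beamlet_coords()
        # (n_patient_voxels, n_beamlets) Gaussian lateral profile
        off2 = (lat[:, None] - bl_lat[None, :]) ** 2 + (z[:, None] - bl_z[None, :]) ** 2
        block = att[:, None] * np.exp(-off2 / (2.0 * sigma_mm**2))
        if prune_rel > 0:
            colmax = block.max(axis=0, keepdims=True)
            block[block < prune_rel * np.maximum(colmax, 1e-300)] = 0.0
        blocks.append(sparse.csr_matrix(block))

    pat_matrix = sparse.hstack(blocks, format="coo")
    full = sparse.csr_matrix(
        (pat_matrix.data, (pat_idx[pat_matrix.row], pat_matrix.col)),
        shape=(grid.n_voxels, pat_matrix.shape[1]),
    )
    full.eliminate_zeros()
    return DoseInfluenceMatrix(full, grid.shape, bs)


def compute_dose(dij: DoseInfluenceMatrix, fluence: np.ndarray) -> np.ndarray:
    """Dose vector (Gy, C-order over the grid) for a fluence vector."""
    x = np.asarray(fluence, float).ravel()
    if x.shape[0] != dij.n_beamlets:
        raise ValueError(
            f"fluence length {x.shape[0]} != beamlet count {dij.n_beamlets}"
        )
    if np.any(x < 0):
        raise ValueError("fluence must be nonnegative")
    return dij.matrix @ x
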