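"""Equi-angular coplanar beam arrangements.

A rotational (VMAT-like) delivery is approximated by many static,
equi-angular coplanar beams — 23 by default, beyond which more beams cost
computation without improving plan quality.  Each beam is a parallel
(source-at-infinity) field discretized into a rectangular grid of
beamlets sized to cover the PTV's projection at that gantry angle plus
one beamlet of margin on every side.

Geometry: beams rotate in the axial (x, y) plane.  At gantry angle ``g``
(degrees) the beam travels along ``u = (sin g, -cos g)`` — angle 0 enters
anteriorly — and the beamlet axes span the perpendicular lateral direction
``l = (cos g, sin g)`` and the cranial-caudal axis ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import StructureSet

__all__ = ["Beam", "BeamSet", "make_beamset", "beam_direction", "lateral_direction"]

DEFAULT_N_BEAMS = 23


def beam_direction(gantry_deg: float) -> np.ndarray:
    """Unit propagation vector of a beam in the axial plane."""
    g = np.deg2rad(gantry_deg)
    return np.array([np.sin(g), -np.cos(g), 0.0])


def lateral_direction(gantry_deg: float) -> np.ndarray:
    """Unit lateral axis of the beamlet grid (perpendicular to the beam)."""
    g = np.deg2rad(gantry_deg)
    return np.array([np.cos(g), np.sin(g), 0.0])


@dataclass(frozen=True)
class Beam:
    """One parallel beam with its beamlet grid.

    ``lateral_positions`` / ``z_positions`` are beamlet-center coordinates
    (mm): lateral along :func:`lateral_direction`, z along the grid's
    cranial-caudal axis.  Beamlets are the cartesian product, lateral
    varying fastest.
    """

    gantry_deg: float
    lateral_positions: np.ndarray
    z_positions: np.ndarray

    @property
    def n_beamlets(self) -> int:
        return len(self.lateral_positions) * len(self.z_positions)

    def beamlet_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lateral, z) coordinates per beamlet, lateral fastest."""
        zz, ll = np.meshgrid(self.z_positions, self.lateral_positions, indexing="ij")
        return ll.ravel(), zz.ravel()


@dataclass(frozen=True)
class BeamSet:
    """An equi-angular set of beams with a common beamlet size."""

    beams: tuple[Beam, ...]
    beamlet_size_mm: float

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    @property
    def n_beamlets(self) -> int:
        return sum(b.n_beamlets for b in self.beams)

    @property
    def gantry_angles_deg(self) -> np.ndarray:
        return np.array([b.gantry_deg for b in self.beams])

    def beamlet_slices(self) -> list[slice]:
        """Per-beam slices into the global beamlet index."""
        out, start = [], 0
        for b in self.beams:
            out.append(slice(start, start + b.n_beamlets))
            start += b.n_beamlets
        return out


def _cover(lo: float, hi: float, step: float) -> np.ndarray:
    """Beamlet centers spaced ``step`` covering [lo, hi] plus one step margin."""
    lo -= step
    hi += step
    n = max(1, int(np.ceil((hi - lo) / step)))
    mid = 0.5 * (lo + hi)
    return mid + (np.arange(n) - (n - 1) / 2.0) * step


def make_beamset(
    ss: StructureSet,
    n_beams: int = DEFAULT_N_BEAMS,
    beamlet_size_mm: float = 6.0,
    target: str = "ptv",
) -> BeamSet:
    """Build an equi-angular beam set whose beamlets cover the target.

    Angles are ``i * 360 / n_beams`` for ``i = 0..n_beams-1``.  For every
    angle the beamlet grid spans the target's projection onto the beam's
    lateral axis (and the z extent in 3-D) plus one beamlet-size margin.
    """
    if n_beams < 1:
        raise ValueError(f"n_beams must be >= 1, got {n_beams}")
    if beamlet_size_mm <= 0:
        raise ValueError(f"beamlet_size_mm must be > 0, got {beamlet_size_mm}")
    tgt = ss[target]
    if not tgt.any():
        raise ValueError(f"target structure {target!r} is empty")
    centers = ss.grid.voxel_centers().reshape(ss.grid.shape + (3,))[tgt]
    angles = np.arange(n_beams) * 360.0 / n_beams

    planar = ss.grid.shape[2] == 1
    beams = []
    for g in angles:
        lat = centers[:, :2] @ lateral_direction(g)[:2]
        lat_pos = _cover(lat.min(), lat.max(), beamlet_size_mm)
        if planar:
            z_pos = np.array([centers[0, 2]])
        else:
            z_pos = _cover(centers[:, 2].min(), centers[:, 2].max(), beamlet_size_mm)
        beams.append(Beam(float(g), lat_pos, z_pos))
    return BeamSet(tuple(beams), float(beamlet_size_mm))
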