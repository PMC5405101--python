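"""HDF5 persistence for phantoms, dose-influence matrices and plans.

Layout conventions: one dataset per mask under ``/masks``, grid metadata
as root attributes, sparse matrices in CSR triplet layout.  Every file
records the package version and, when supplied, the seed and a config
hash, so reruns are traceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from scipy import sparse

from . import __version__
from .beams import Beam, BeamSet
from .grid import VoxelGrid
from .influence import DoseInfluenceMatrix, Plan
from .prescription import Prescription
from .structures import StructureSet

__all__ = ["save_phantom", "load_phantom", "save_dij", "load_dij", "save_plan", "load_plan"]


def _stamp(f: h5py.File, seed: int | None = None, config_hash: str | None = None) -> None:
    f.attrs["tool_version"] = __version__
    if seed is not None:
        f.attrs["seed"] = int(seed)
    if config_hash is not None:
        f.attrs["config_hash"] = config_hash


def save_phantom(ss: StructureSet, path: str | Path, seed: int | None = None,
                 config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, seed, config_hash)
        f.attrs["grid_shape"] = ss.grid.shape
        f.attrs["grid_spacing"] = ss.grid.spacing
        f.attrs["grid_origin"] = ss.grid.origin
        grp = f.create_group("masks")
        for name, mask in ss.masks.items():
            d = grp.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")
            d.attrs["role"] = ss.roles.get(name, "derived")


def load_phantom(path: str | Path) -> StructureSet:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(
            tuple(int(v) for v in f.attrs["grid_shape"]),
            tuple(float(v) for v in f.attrs["grid_spacing"]),
            tuple(float(v) for v in f.attrs["grid_origin"]),
        )
        ss = StructureSet(grid)
        for name, d in f["masks"].items():
            ss.add(name, d[()].astype(bool), d.attrs.get("role", "derived"))
    return ss


def save_dij(dij: DoseInfluenceMatrix, path: str | Path, seed: int | None = None) -> None:
    m = dij.matrix.tocsr()
    with h5py.File(path, "w") as f:
        _stamp(f, seed)
        f.attrs["shape"] = m.shape
        f.attrs["grid_shape"] = dij.grid_shape
        f.attrs["beamlet_size_mm"] = dij.beamset.beamlet_size_mm
        f.create_dataset("data", data=m.data, compression="gzip")
        f.create_dataset("indices", data=m.indices, compression="gzip")
        f.create_dataset("indptr", data=m.indptr, compression="gzip")
        beams = f.create_group("beams")
        for i, b in enumerate(dij.beamset.beams):
            g = beams.create_group(f"{i:03d}")
            g.attrs["gantry_deg"] = b.gantry_deg
            g.create_dataset("lateral_positions", data=b.lateral_positions)
            g.create_dataset("z_positions", data=b.z_positions)


def load_dij(path: str | Path) -> DoseInfluenceMatrix:
    with h5py.File(path, "r") as f:
        m = sparse.csr_matrix(
            (f["data"][()], f["indices"][()], f["indptr"][()]),
            shape=tuple(f.attrs["shape"]),
        )
        beams = []
        for key in sorted(f["beams"]):
            g = f["beams"][key]
            beams.append(Beam(
                float(g.attrs["gantry_deg"]),
                g["lateral_positions"][()],
                g["z_positions"][()],
            ))
        bs = BeamSet(tuple(beams), float(f.attrs["beamlet_size_mm"]))
        grid_shape = tuple(int(v) for v in f.attrs["grid_shape"])
    return DoseInfluenceMatrix(m, grid_shape, bs)


def save_plan(plan: Plan, path: str | Path, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, seed)
        f.create_dataset("fluence", data=plan.fluence, compression="gzip")
        f.create_dataset("dose", data=plan.dose, compression="gzip")
        if plan.prescription is not None:
            f.attrs["prescription"] = json.dumps(plan.prescription.to_dict())
        if plan.wishlist_name:
            f.attrs["wishlist_name"] = plan.wishlist_name
        if plan.solver_log is not None:
            f.attrs["solver_log"] = json.dumps(plan.solver_log)


def load_plan(path: str | Path) -> Plan:
    with h5py.File(path, "r") as f:
        rx = None
        if "prescription" in f.attrs:
            rx = Prescription.from_dict(json.loads(f.attrs["prescription"]))
        log = None
        if "solver_log" in f.attrs:
            log = json.loads(f.attrs["solver_log"])
        return Plan(
            f["fluence"][()],
            f["dose"][()],
            rx,
            f.attrs.get("wishlist_name"),
            log,
        )
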