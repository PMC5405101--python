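"""Glue helpers shared by optimizer-facing tests."""

import numpy as np
from scipy import sparse

import prioplan as pp
from prioplan.grid import VoxelGrid
from prioplan.influence import DoseInfluenceMatrix
from prioplan.structures import StructureSet
from prioplan.wishlist import Wishlist


def tiny_problem(D, volumes, constraints, objectives, name="toy"):
    """Wrap dense matrices/masks into the optimizer's input types.

    ``volumes``: name -> boolean mask over the n_vox flat voxels (stored on
    a fake (n_vox, 1, 1) grid).
    """
    n_vox = D.shape[0]
    grid = VoxelGrid((n_vox, 1, 1), (1.0, 1.0, 1.0))
    ss = StructureSet(grid)
    ss.add("patient", np.ones((n_vox, 1, 1), bool))
    for vname, mask in volumes.items():
        ss.add(vname, np.asarray(mask, bool).reshape(n_vox, 1, 1))
    bs = pp.make_beamset(ss, n_beams=1, target="patient")
    dij = DoseInfluenceMatrix(sparse.csr_matrix(D), grid.shape, bs)
    wl = Wishlist(name, constraints, objectives)
    wl.validate()
    return dij, wl, ss


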