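import numpy as np
import pytest

import biotite.structure as struc

from hemetrics import build_minimal_basis, StructureModel
from hemetrics.synthetic import make_reference_porphyrin


@pytest.fixture(scope="session")
def basis():
    return build_minimal_basis("group-theoretic")


@pytest.fixture(scope="session")
def static_basis():
    return build_minimal_basis("static-table")


@pytest.fixture()
def reference_core():
    return make_reference_porphyrin()


def build_model(atoms, entry_id="TEST"):
    """Build a StructureModel from (chain, res_id, res_name, atom_name,
    element, xyz[, occupancy]) tuples."""
    arr = struc.AtomArray(len(atoms))
    occ = np.ones(len(atoms))
    for i, a in enumerate(atoms):
        chain, res_id, res_name, atom_name, element, xyz = a[:6]
        if len(a) > 6:
            occ[i] = a[6]
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = element
        arr.coord[i] = xyz
    arr.hetero[:] = ~struc.filter_amino_acids(arr)
    arr.set_annotation("occupancy", occ)
    arr.set_annotation("b_factor", np.zeros(len(atoms)))
    return StructureModel(atoms=arr, entry_id=entry_id)


def core_as_model(core, extra=()):
    """StructureModel holding a PorphyrinCore plus optional extra atoms."""
    from hemetrics.reference import CANONICAL_ATOMS

    rows = []
    for name, xyz in zip(CANONICAL_ATOMS, core.core_coords):
        el = "N" if name.startswith("N") else "C"
        rows.append((core.chain_id, core.res_id, core.res_name, name, el, xyz))
    rows.append((core.chain_id, core.res_id, core.res_name, "FE", "FE",
                 core.fe_coord))
    next_res = core.res_id + 1
    for res_name, atom_name, element, xyz in tuple(core.extra_atoms) + tuple(extra):
        rows.append((core.chain_id, next_res, res_name, atom_name, element,
                     xyz))
        next_res += 1
    return build_model(rows, entry_id=core.entry_id or "TEST")


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans
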