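"""Heme-site geometry: axial ligands, cross-link, H-bonds, hybridization, pocket."""

import numpy as np
import pytest

from hemetrics import (
    axial_ligands,
    characterize_heme_site,
    detect_crosslink,
    extract_porphyrin_cores,
    hydrogen_bonds,
    meso_hybridization,
    pocket_residues,
    select_atoms,
)
from hemetrics.geometry import hydrophobicity_class
from hemetrics.synthetic import (
    DistortionSpec,
    apply_distortion,
    make_reference_porphyrin,
)

from conftest import build_model, core_as_model, random_rigid_motion


@pytest.fixture()
def p460_like():
    """Synthetic six-coordinate, cross-linked site (distances are inputs)."""
    core = apply_distortion(
        make_reference_porphyrin(),
        DistortionSpec(amplitudes={"ruf": 0.5}, axial_o_distance=2.43,
                       lys_nz=("CHC", 1.34)))
    return core_as_model(core), core


@pytest.fixture()
def bare_heme():
    core = make_reference_porphyrin()
    return core_as_model(core), core


def test_axial_o_at_exact_distance(bare_heme):
    model, core = bare_heme
    o = core.fe_coord + np.array([0.0, 0.0, 2.50])
    model2 = core_as_model(core, extra=[("HOH", "O", "O", tuple(o))])
    ligands = axial_ligands(model2, core)
    assert len(ligands) == 1
    assert ligands[0].side == "distal"
    assert ligands[0].distance == pytest.approx(2.50, abs=1e-6)


def test_vacant_site_is_empty_list(bare_heme):
    model, core = bare_heme
    assert axial_ligands(model, core) == []


def test_low_occupancy_water_excluded(bare_heme):
    _, core = bare_heme
    o = tuple(core.fe_coord + np.array([0.0, 0.0, 2.4]))
    from hemetrics.reference import CANONICAL_ATOMS

    rows = []
    for name, xyz in zip(CANONICAL_ATOMS, core.core_coords):
        el = "N" if name.startswith("N") else "C"
        rows.append(("A", 1, "HEM", name, el, xyz))
    rows.append(("A", 1, "HEM", "FE", "FE", core.fe_coord))
    rows.append(("A", 2, "HOH", "O", "O", o, 0.3))   # occupancy 0.3
    model = build_model(rows)
    assert axial_ligands(model, core) == []


def test_crosslink_detected_and_distance(p460_like):
    model, core = p460_like
    rec = detect_crosslink(model, core)
    assert rec is not None
    assert rec.meso_label == "CHC"
    assert rec.distance == pytest.approx(1.34, abs=1e-6)


def test_crosslink_absent_above_cutoff(bare_heme):
    _, base = bare_heme
    core = apply_distortion(make_reference_porphyrin(),
                            DistortionSpec(lys_nz=("CHC", 2.5)))
    model = core_as_model(core)
    assert detect_crosslink(model, core) is None


def test_crosslink_absent_without_lysine(bare_heme):
    model, core = bare_heme
    assert detect_crosslink(model, core) is None


def test_hbond_found_at_3p1_and_not_at_4p0(bare_heme):
    _, core = bare_heme
    o1 = core.fe_coord + np.array([0.0, 0.0, 2.43])
    for d, expect in ((3.1, 1), (4.0, 0)):
        o2 = o1 + np.array([d, 0.0, 0.0])
        model = core_as_model(core, extra=[
            ("HOH", "O", "O", tuple(o1)),
            ("ASP", "OD1", "O", tuple(o2))])
        focus = select_atoms(model, res_name="HOH")
        bonds = [h for h in hydrogen_bonds(model, focus)
                 if {a.res_name for a in h.donor_acceptor} == {"HOH", "ASP"}]
        assert len(bonds) == expect, f"separation {d}"
        if expect:
            assert bonds[0].distance == pytest.approx(3.1, abs=1e-6)


def test_hbond_excludes_same_residue_and_covalent():
    p = np.array([20.0, 0.0, 0.0])
    rows = [
        ("A", 5, "SER", "OG", "O", tuple(p)),
        ("A", 5, "SER", "N", "N", tuple(p + [3.0, 0, 0])),   # same residue
        ("A", 6, "GLY", "N", "N", tuple(p + [0, 1.4, 0])),   # covalent range
    ]
    model = build_model(rows)
    focus = select_atoms(model, res_name="SER", atom_name="OG")
    assert hydrogen_bonds(model, focus) == []


def test_meso_hybridization_trigonal_vs_tetrahedral():
    c = np.array([0.0, 0.0, 0.0])
    rows = [("A", 1, "HEM", "CHA", "C", tuple(c))]
    # trigonal planar: three neighbours at 120 degrees in the plane
    for k, (name, rn, rid) in enumerate((("C1A", "HEM", 1),
                                         ("C4D", "HEM", 1),
                                         ("NZ", "LYS", 2))):
        a = 2 * np.pi * k / 3
        rows.append(("A", rid, rn, name, "C" if name != "NZ" else "N",
                     (1.45 * np.cos(a), 1.45 * np.sin(a), 0.0)))
    model = build_model(rows)
    core = make_reference_porphyrin()
    # fake core whose CHA sits at the constructed carbon
    coords = np.array(core.core_coords)
    from hemetrics.reference import ATOM_INDEX
    coords[ATOM_INDEX["CHA"]] = c
    core2 = type(core)(core_coords=coords, fe_coord=core.fe_coord)
    m = meso_hybridization(model, core2, "CHA")
    assert m.verdict == "sp2-like"
    assert m.angle_sum == pytest.approx(360.0, abs=1e-6)
    assert m.oop_displacement == pytest.approx(0.0, abs=1e-9)

    # tetrahedral: three of four sp3 directions -> angle sum 3 x 109.47
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1]]) / np.sqrt(3)
    rows = [("A", 1, "HEM", "CHA", "C", tuple(c))]
    for k, d in enumerate(dirs):
        rows.append(("A", 1, "HEM", f"X{k}", "C", tuple(1.5 * d)))
    m = meso_hybridization(build_model(rows), core2, "CHA")
    assert m.angle_sum == pytest.approx(3 * 109.4712, abs=0.01)
    assert m.verdict == "sp3-like"


def test_meso_hybridization_needs_three_neighbours(bare_heme):
    model, core = bare_heme
    # un-crosslinked meso in an H-less structure has only 2 heavy neighbours
    m = meso_hybridization(model, core, "CHA")
    assert m.verdict == "indeterminate"
    assert "2 covalent neighbours" in m.reason


def test_crosslinked_meso_is_sp2_like(p460_like):
    model, core = p460_like
    m = meso_hybridization(model, core, "CHC")
    assert m.verdict == "sp2-like"


def test_pocket_residues_empty_for_bare_heme(bare_heme):
    model, core = bare_heme
    assert pocket_residues(model, core, "distal") == []
    assert pocket_residues(model, core, "proximal") == []


def test_pocket_residue_classification_and_side(bare_heme):
    _, core = bare_heme
    up = core.fe_coord + np.array([2.0, 0.0, 4.0])
    down = core.fe_coord + np.array([0.0, 2.0, -4.0])
    model = core_as_model(core, extra=[
        ("ARG", "CZ", "C", tuple(up)),
        ("PHE", "CZ", "C", tuple(down))])
    distal = pocket_residues(model, core, "distal")
    proximal = pocket_residues(model, core, "proximal")
    assert [r.res_name for r in distal] == ["ARG"]
    assert distal[0].hydrophobicity == "charged"
    assert [r.res_name for r in proximal] == ["PHE"]
    assert proximal[0].hydrophobicity == "hydrophobic"


def test_hydrophobicity_table():
    assert hydrophobicity_class("LEU") == "hydrophobic"
    assert hydrophobicity_class("GLN") == "polar"
    assert hydrophobicity_class("ASP") == "charged"
    assert hydrophobicity_class("HEM") == "other"


def test_distances_rigid_motion_invariant(p460_like):
    model, core = p460_like
    d0 = detect_crosslink(model, core).distance
    a0 = axial_ligands(model, core)[0].distance
    rng = np.random.default_rng(9)
    rot, trans = random_rigid_motion(rng)
    atoms = model.atoms.copy()
    atoms.coord = atoms.coord @ rot.T + trans
    from hemetrics.structure import StructureModel
    moved_model = StructureModel(atoms=atoms, entry_id="MOVED")
    moved_core = type(core)(
        core_coords=core.core_coords @ rot.T + trans,
        fe_coord=rot @ core.fe_coord + trans)
    assert detect_crosslink(moved_model, moved_core).distance == \
        pytest.approx(d0, abs=1e-5)   # biotite stores coords as float32
    assert axial_ligands(moved_model, moved_core)[0].distance == \
        pytest.approx(a0, abs=1e-5)


def test_characterize_heme_site_aggregates(p460_like):
    model, core = p460_like
    site = characterize_heme_site(model, core)
    assert site.crosslink is not None
    assert any(l.side == "distal" for l in site.axial)
    assert len(site.meso) == 4
    d = site.as_dict()
    assert d["crosslink"]["distance"] == 1.34
    assert d["axial_ligands"][0]["distance"] == 2.43
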