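"""Heme-site geometric characterization.

Distance-based observables of a heme pocket as read from a crystal
structure: axial Fe ligands, the porphyrin-lysine covalent cross-link that
defines cytochrome P460 cofactors, donor-acceptor hydrogen bonds, meso
carbon hybridization metrics, and a pocket residue inventory with
hydrophobicity classes.

Crystal structures at the resolutions of interest carry no hydrogens, so
hydrogen bonding is assessed by the standard crystallographic
donor-acceptor distance criterion (N/O/S pairs within 3.5 Angstrom)
rather than by explicit H geometry.  Distal and proximal sides are assigned
by the sign of the z coordinate in the mean-plane-aligned frame: the
proximal side is the one carrying the His ligand (or, failing that, the
side the iron displaces toward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .nsd import AlignedCore, align_to_mean_plane
from .structure import PorphyrinCore, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_AXIAL_CUTOFF = 3.0       # Angstrom, Fe-ligand detection
DEFAULT_COVALENT_CUTOFF = 1.8    # Angstrom, covalent bonds
DEFAULT_HBOND_CUTOFF = 3.5       # Angstrom, donor-acceptor
HBOND_MIN_DISTANCE = 2.2         # below this a contact is covalent, not an H-bond
DEFAULT_POCKET_RADIUS = 8.0      # Angstrom from Fe
WATER_NAMES = ("HOH", "WAT")
_ELEMENTS_NOS = ("N", "O", "S")

# fixed residue-type table (one-letter classes documented in methods note)
HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO",
               "GLY", "CYS"}
POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "HIS"}
CHARGED = {"ASP", "GLU", "LYS", "ARG"}

SP2_ANGLE_SUM_MIN = 355.0        # degrees
SP2_OOP_MAX = 0.15               # Angstrom
SP3_ANGLE_SUM_MAX = 345.0        # degrees; below this, clearly pyramidal


@dataclass(frozen=True)
class AtomRef:
    """Identification of one atom in a structure."""
    chain_id: str
    res_name: str
    res_id: int
    atom_name: str

    def __str__(self):
        return f"{self.chain_id}/{self.res_name} {self.res_id}/{self.atom_name}"


@dataclass(frozen=True)
class AxialLigand:
    side: str                     # "distal" or "proximal"
    atom: AtomRef
    distance: float               # Fe-atom, Angstrom
    z: float                      # signed z in the aligned frame


@dataclass(frozen=True)
class CrosslinkRecord:
    lysine_chain: str
    lysine_res_id: int
    nz_coord: tuple
    meso_label: str
    meso_coord: tuple
    distance: float


@dataclass(frozen=True)
class HBond:
    donor_acceptor: tuple         # (AtomRef, AtomRef); roles indistinguishable
    distance: float


@dataclass(frozen=True)
class HybridizationMetrics:
    meso_label: str
    substituents: tuple           # AtomRefs of the three neighbours
    angle_sum: float | None       # degrees
    oop_displacement: float | None  # Angstrom
    verdict: str                  # sp2-like | sp3-like | indeterminate
    reason: str = ""


@dataclass(frozen=True)
class PocketResidue:
    chain_id: str
    res_name: str
    res_id: int
    min_distance: float           # nearest atom to Fe, Angstrom
    hydrophobicity: str           # hydrophobic | polar | charged | other


def hydrophobicity_class(res_name: str) -> str:
    res_name = res_name.upper()
    if res_name in HYDROPHOBIC:
        return "hydrophobic"
    if res_name in POLAR:
        return "polar"
    if res_name in CHARGED:
        return "charged"
    return "other"


def _atom_ref(atoms, i) -> AtomRef:
    return AtomRef(chain_id=str(atoms.chain_id[i]),
                   res_name=str(atoms.res_name[i]),
                   res_id=int(atoms.res_id[i]),
                   atom_name=str(atoms.atom_name[i]).strip())


def _aligned_frame(model: StructureModel, core: PorphyrinCore) -> AlignedCore:
    """Aligned frame with the proximal side (His ligand if any) at -z."""
    prox = _proximal_his_coord(model, core)
    return align_to_mean_plane(core, proximal_coord=prox)


def _proximal_his_coord(model: StructureModel,
                        core: PorphyrinCore) -> np.ndarray | None:
    atoms = model.atoms
    fe = np.asarray(core.fe_coord)
    is_his_n = ((atoms.res_name == "HIS")
                & np.isin(atoms.atom_name, ("ND1", "NE2")))
    if not np.any(is_his_n):
        return None
    cand = atoms[is_his_n]
    d = np.linalg.norm(cand.coord - fe, axis=1)
    i = int(np.argmin(d))
    if d[i] > DEFAULT_AXIAL_CUTOFF:
        return None
    return np.asarray(cand.coord[i])


def axial_ligands(model: StructureModel, core: PorphyrinCore,
                  cutoff: float = DEFAULT_AXIAL_CUTOFF) -> list[AxialLigand]:
    """All candidate axial ligand atoms within ``cutoff`` of the iron.

    Candidates are N/O/S atoms outside the heme residue itself, sorted by
    Fe distance.  Waters with occupancy below 0.5 are excluded.  An empty
    list on one side means the iron is five-coordinate on that side.
    """
    atoms = model.atoms
    fe = np.asarray(core.fe_coord)
    aligned = _aligned_frame(model, core)

    sel = np.isin(atoms.element, _ELEMENTS_NOS)
    sel &= ~((atoms.chain_id == core.chain_id)
             & (atoms.res_id == core.res_id)
             & (atoms.res_name == core.res_name))
    if "occupancy" in atoms.get_annotation_categories():
        low_occ_water = (np.isin(atoms.res_name, WATER_NAMES)
                         & (atoms.occupancy < 0.5))
        sel &= ~low_occ_water
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return []
    d = np.linalg.norm(atoms.coord[idx] - fe, axis=1)
    keep = d <= cutoff
    idx, d = idx[keep], d[keep]

    out = []
    for i, dist in sorted(zip(idx, d), key=lambda t: t[1]):
        rel = aligned.rotation @ (atoms.coord[i] - aligned.translation)
        z = float(rel[2])
        side = "proximal" if z < 0 else "distal"
        out.append(AxialLigand(side=side, atom=_atom_ref(atoms, i),
                               distance=float(dist), z=z))
    return out


def detect_crosslink(model: StructureModel, core: PorphyrinCore,
                     covalent_cutoff: float = DEFAULT_COVALENT_CUTOFF
                     ) -> CrosslinkRecord | None:
    """The porphyrin-Lys cross-link, if a lysine NZ sits within covalent
    range of a meso carbon; ``None`` otherwise.

    The cross-linked meso carbon is identified operationally as whichever
    CHA-CHD atom carries the NZ; no IUPAC renumbering is attempted.
    """
    atoms = model.atoms
    is_nz = (atoms.res_name == "LYS") & (atoms.atom_name == "NZ")
    if not np.any(is_nz):
        return None
    nz = atoms[is_nz]
    best = None
    for label, mcoord in core.meso_coords().items():
        d = np.linalg.norm(nz.coord - mcoord, axis=1)
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (float(d[i]), label, mcoord, i)
    dist, label, mcoord, i = best
    if dist > covalent_cutoff:
        return None
    return CrosslinkRecord(
        lysine_chain=str(nz.chain_id[i]), lysine_res_id=int(nz.res_id[i]),
        nz_coord=tuple(float(v) for v in nz.coord[i]),
        meso_label=label, meso_coord=tuple(float(v) for v in mcoord),
        distance=dist)


def select_atoms(model: StructureModel, chain_id: str | None = None,
                 res_name: str | None = None, res_id: int | None = None,
                 atom_name: str | None = None) -> np.ndarray:
    """Boolean mask over the model's atoms matching all given criteria."""
    atoms = model.atoms
    mask = np.ones(atoms.array_length(), dtype=bool)
    if chain_id is not None:
        mask &= atoms.chain_id == chain_id
    if res_name is not None:
        mask &= atoms.res_name == res_name
    if res_id is not None:
        mask &= atoms.res_id == res_id
    if atom_name is not None:
        mask &= atoms.atom_name == atom_name
    return mask


def hydrogen_bonds(model: StructureModel, focus: np.ndarray,
                   cutoff: float = DEFAULT_HBOND_CUTOFF) -> list[HBond]:
    """Donor-acceptor contacts involving at least one focus atom.

    ``focus`` is a boolean mask over the model's atoms (see
    :func:`select_atoms`).  Partners must both be N/O/S; pairs within one
    residue are excluded, as are contacts short enough to be covalent
    (< 2.2 Angstrom).  With no hydrogens in the model, donor and acceptor
    roles are not distinguishable and the pair is reported unordered.
    """
    atoms = model.atoms
    focus = np.asarray(focus, dtype=bool)
    if focus.shape != (atoms.array_length(),):
        raise ValueError("focus must be a boolean mask over the model's atoms")
    nos = np.isin(atoms.element, _ELEMENTS_NOS)
    idx = np.flatnonzero(nos)
    if idx.size == 0:
        return []
    tree = cKDTree(atoms.coord[idx])
    pairs = tree.query_pairs(cutoff)
    bonds = []
    for a, b in pairs:
        i, j = int(idx[a]), int(idx[b])
        if not (focus[i] or focus[j]):
            continue
        same_res = (atoms.chain_id[i] == atoms.chain_id[j]
                    and atoms.res_id[i] == atoms.res_id[j]
                    and atoms.res_name[i] == atoms.res_name[j])
        if same_res:
            continue
        d = float(np.linalg.norm(atoms.coord[i] - atoms.coord[j]))
        if d < HBOND_MIN_DISTANCE:
            continue
        bonds.append(HBond(donor_acceptor=(_atom_ref(atoms, i),
                                           _atom_ref(atoms, j)),
                           distance=d))
    bonds.sort(key=lambda h: h.distance)
    return bonds


def meso_hybridization(model: StructureModel, core: PorphyrinCore,
                       meso: str,
                       angle_sum_sp2: float = SP2_ANGLE_SUM_MIN,
                       oop_sp2: float = SP2_OOP_MAX) -> HybridizationMetrics:
    """Hybridization metrics of one meso carbon (CHA-CHD).

    With exactly three covalent neighbours (including a cross-linked NZ if
    present), the sum of the three bond angles at the carbon and its
    displacement from the substituent plane discriminate sp2 (planar,
    angle sum 360) from sp3 (pyramidal, angle sum near 328.4 = 3 x 109.47).
    """
    if meso not in core.meso_ids:
        raise ValueError(f"unknown meso label {meso!r}")
    atoms = model.atoms
    c = core.atom_coord(meso)
    d = np.linalg.norm(atoms.coord - c, axis=1)
    near = np.flatnonzero((d > 1e-6) & (d <= DEFAULT_COVALENT_CUTOFF)
                          & (atoms.element != "H"))
    if near.size != 3:
        return HybridizationMetrics(
            meso_label=meso, substituents=tuple(_atom_ref(atoms, i)
                                                for i in near),
            angle_sum=None, oop_displacement=None, verdict="indeterminate",
            reason=f"{near.size} covalent neighbours (need 3)")
    vs = atoms.coord[near] - c
    angle = 0.0
    for a, b in ((0, 1), (1, 2), (0, 2)):
        cosang = vs[a] @ vs[b] / (np.linalg.norm(vs[a]) * np.linalg.norm(vs[b]))
        angle += np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    # distance of the meso carbon from the plane through its 3 substituents
    p0, p1, p2 = atoms.coord[near]
    n = np.cross(p1 - p0, p2 - p0)
    n /= np.linalg.norm(n)
    oop = float(abs((c - p0) @ n))
    if angle >= angle_sum_sp2 and oop <= oop_sp2:
        verdict = "sp2-like"
    elif angle <= SP3_ANGLE_SUM_MAX:
        verdict = "sp3-like"
    else:
        verdict = "indeterminate"
    return HybridizationMetrics(
        meso_label=meso,
        substituents=tuple(_atom_ref(atoms, i) for i in near),
        angle_sum=float(angle), oop_displacement=oop, verdict=verdict)


def pocket_residues(model: StructureModel, core: PorphyrinCore, side: str,
                    radius: float = DEFAULT_POCKET_RADIUS
                    ) -> list[PocketResidue]:
    """Amino-acid residues within ``radius`` of the iron on one side.

    A residue is assigned to the side (by the aligned-frame z sign) of its
    atom nearest to the iron, and residues are returned sorted by that
    minimal distance.  Waters and the heme itself are excluded.
    """
    if side not in ("distal", "proximal"):
        raise ValueError("side must be 'distal' or 'proximal'")
    atoms = model.atoms
    fe = np.asarray(core.fe_coord)
    aligned = _aligned_frame(model, core)

    import biotite.structure as struc
    aa = struc.filter_amino_acids(atoms)
    idx = np.flatnonzero(aa)
    if idx.size == 0:
        return []
    d = np.linalg.norm(atoms.coord[idx] - fe, axis=1)
    within = d <= radius
    best: dict[tuple, tuple] = {}
    for i, dist in zip(idx[within], d[within]):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.res_name[i]))
        if key not in best or dist < best[key][0]:
            best[key] = (float(dist), int(i))
    out = []
    for (chain, res_id, res_name), (dist, i) in best.items():
        rel = aligned.rotation @ (atoms.coord[i] - aligned.translation)
        res_side = "proximal" if rel[2] < 0 else "distal"
        if res_side != side:
            continue
        out.append(PocketResidue(chain_id=chain, res_name=res_name,
                                 res_id=res_id, min_distance=dist,
                                 hydrophobicity=hydrophobicity_class(res_name)))
    out.sort(key=lambda r: r.min_distance)
    return out


@dataclass(frozen=True)
class HemeSiteReport:
    """Aggregate heme-site characterization of one core."""

    entry_id: str
    chain_id: str
    res_id: int
    fe_oop: float                         # signed Fe out-of-plane offset
    axial: tuple                          # AxialLigand
    crosslink: CrosslinkRecord | None
    hbonds_to_axial: tuple                # HBond, around axial ligands
    meso: tuple                           # HybridizationMetrics for CHA-CHD
    pocket_distal: tuple                  # PocketResidue
    pocket_proximal: tuple

    def as_dict(self) -> dict:
        def ligand(l):
            return {"side": l.side, "atom": str(l.atom),
                    "distance": round(l.distance, 2)}
        return {
            "entry": self.entry_id, "chain": self.chain_id,
            "res_id": self.res_id,
            "fe_oop": round(self.fe_oop, 3),
            "axial_ligands": [ligand(l) for l in self.axial],
            "crosslink": (None if self.crosslink is None else {
                "lysine": f"{self.crosslink.lysine_chain}/"
                          f"{self.crosslink.lysine_res_id}",
                "meso": self.crosslink.meso_label,
                "distance": round(self.crosslink.distance, 2)}),
            "hbonds_to_axial": [
                {"pair": [str(a) for a in h.donor_acceptor],
                 "distance": round(h.distance, 1)}
                for h in self.hbonds_to_axial],
            "meso_hybridization": [
                {"meso": m.meso_label, "verdict": m.verdict,
                 "angle_sum": (None if m.angle_sum is None
                               else round(m.angle_sum, 1)),
                 "oop": (None if m.oop_displacement is None
                         else round(m.oop_displacement, 3))}
                for m in self.meso],
            "pocket_distal": [
                {"residue": f"{r.chain_id}/{r.res_name} {r.res_id}",
                 "distance": round(r.min_distance, 2),
                 "class": r.hydrophobicity} for r in self.pocket_distal],
            "pocket_proximal": [
                {"residue": f"{r.chain_id}/{r.res_name} {r.res_id}",
                 "distance": round(r.min_distance, 2),
                 "class": r.hydrophobicity} for r in self.pocket_proximal],
        }


def characterize_heme_site(model: StructureModel, core: PorphyrinCore,
                           axial_cutoff: float = DEFAULT_AXIAL_CUTOFF,
                           covalent_cutoff: float = DEFAULT_COVALENT_CUTOFF,
                           hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                           pocket_radius: float = DEFAULT_POCKET_RADIUS
                           ) -> HemeSiteReport:
    """Run the full heme-site battery on one core."""
    aligned = _aligned_frame(model, core)
    axial = axial_ligands(model, core, cutoff=axial_cutoff)
    xlink = detect_crosslink(model, core, covalent_cutoff=covalent_cutoff)
    hb: list[HBond] = []
    for lig in axial:
        focus = select_atoms(model, chain_id=lig.atom.chain_id,
                             res_name=lig.atom.res_name,
                             res_id=lig.atom.res_id,
                             atom_name=lig.atom.atom_name)
        hb.extend(hydrogen_bonds(model, focus, cutoff=hbond_cutoff))
    meso = tuple(meso_hybridization(model, core, m) for m in core.meso_ids)
    return HemeSiteReport(
        entry_id=core.entry_id, chain_id=core.chain_id, res_id=core.res_id,
        fe_oop=aligned.fe_oop, axial=tuple(axial), crosslink=xlink,
        hbonds_to_axial=tuple(hb), meso=meso,
        pocket_distal=tuple(pocket_residues(model, core, "distal",
                                            pocket_radius)),
        pocket_proximal=tuple(pocket_residues(model, core, "proximal",
                                              pocket_radius)))
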