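"""Reading macromolecular structures and extracting canonically ordered heme cores.

PDB and mmCIF parsing is delegated to biotite; this module's job is the
domain logic on top: altloc policy, heme residue discovery, mapping PDB
atom names onto the canonical 24-atom macrocycle order and validating that
the extracted atoms really form a porphyrin macrocycle.

Entry ids are accepted as local file paths only; nothing here touches the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx

from .reference import (
    ATOM_INDEX,
    CANONICAL_ATOMS,
    MESO_ATOMS,
    NITROGEN_ATOMS,
    macrocycle_bonds,
)

logger = logging.getLogger(__name__)

#: residue names recognized as heme groups (b- and c-type nomenclature)
DEFAULT_HEME_NAMES: tuple[str, ...] = ("HEM", "HEC", "HEB")

#: altloc identifiers retained when alternates are present
_KEPT_ALTLOCS = ("", " ", ".", "A")

#: bond-length window (Angstrom) for the macrocycle adjacency graph
BOND_WINDOW = (1.2, 1.7)


class StructureParseError(ValueError):
    """File could not be parsed under the named standard."""


class EmptyStructureError(ValueError):
    """Parsed file contains no atoms."""


@dataclass
class StructureModel:
    """First model of a crystal structure: an atom array plus entry metadata."""

    atoms: struc.AtomArray
    entry_id: str = ""

    def __post_init__(self):
        if self.atoms.array_length() == 0:
            raise EmptyStructureError(f"structure {self.entry_id!r} has no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureParseError(
                f"structure {self.entry_id!r} contains non-finite coordinates")

    def __len__(self) -> int:
        return self.atoms.array_length()


@dataclass
class PorphyrinCore:
    """A 24-atom porphyrin macrocycle in canonical order, plus its iron.

    ``core_coords[i]`` is the coordinate of canonical atom
    ``CANONICAL_ATOMS[i]``.  ``extra_atoms`` carries optional companion
    atoms (axial ligand, cross-link pseudo-atoms) used by the synthetic
    fixture writer; they are not part of the macrocycle.
    """

    core_coords: np.ndarray              # (24, 3) Angstrom
    fe_coord: np.ndarray                 # (3,) Angstrom
    chain_id: str = "A"
    res_name: str = "HEM"
    res_id: int = 1
    entry_id: str = ""
    extra_atoms: tuple = ()              # (res_name, atom_name, element, xyz)

    meso_ids: tuple[str, ...] = MESO_ATOMS

    def __post_init__(self):
        self.core_coords = np.asarray(self.core_coords, dtype=float)
        self.fe_coord = np.asarray(self.fe_coord, dtype=float)
        if self.core_coords.shape != (24, 3):
            raise ValueError("core_coords must be (24, 3)")

    def atom_coord(self, name: str) -> np.ndarray:
        return self.core_coords[ATOM_INDEX[name]]

    def meso_coords(self) -> dict[str, np.ndarray]:
        return {m: self.atom_coord(m) for m in self.meso_ids}

    def nitrogen_centroid(self) -> np.ndarray:
        idx = [ATOM_INDEX[n] for n in NITROGEN_ATOMS]
        return self.core_coords[idx].mean(axis=0)

    def validate(self) -> None:
        """Raise ValueError if the macrocycle invariants do not hold."""
        if not np.all(np.isfinite(self.core_coords)):
            raise ValueError("non-finite core coordinates")
        ok, why = _is_macrocycle(self.core_coords)
        if not ok:
            raise ValueError(f"not a porphyrin macrocycle: {why}")
        d = np.linalg.norm(self.fe_coord - self.nitrogen_centroid())
        if d > 2.5:
            raise ValueError(f"Fe is {d:.2f} A from the 4-N centroid (> 2.5)")


def _is_macrocycle(coords: np.ndarray,
                   window: tuple[float, float] = BOND_WINDOW) -> tuple[bool, str]:
    """Check that the 24 atoms form the porphine macrocycle bond graph.

    All 28 expected bonds must fall inside the bond-length window and no
    unexpected pair may; this guarantees a single closed macrocycle in
    which every atom lies on a ring.
    """
    lo, hi = window
    expected = {tuple(sorted(b)) for b in macrocycle_bonds()}
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    for i, j in expected:
        if not (lo <= dist[i, j] <= hi):
            return False, (f"bond {CANONICAL_ATOMS[i]}-{CANONICAL_ATOMS[j]} "
                           f"= {dist[i, j]:.2f} A outside [{lo}, {hi}]")
    for i in range(24):
        for j in range(i + 1, 24):
            if (i, j) not in expected and lo <= dist[i, j] <= hi:
                return False, (f"unexpected contact {CANONICAL_ATOMS[i]}-"
                               f"{CANONICAL_ATOMS[j]} = {dist[i, j]:.2f} A")
    return True, ""


def _filter_altlocs(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep altloc 'A' or blank; discard other alternates."""
    if "altloc_id" not in atoms.get_annotation_categories():
        return atoms
    keep = np.isin(atoms.altloc_id, _KEPT_ALTLOCS)
    return atoms[keep]


def read_structure(path, fmt: str = "auto", entry_id: str | None = None
                   ) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  Altloc policy:
    keep 'A' or blank, discard others.  ``fmt`` may be ``pdb``, ``mmcif``
    or ``auto`` (by file suffix, defaulting to PDB).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {fmt!r}")

    kwargs = dict(model=1, altloc="all",
                  extra_fields=["occupancy", "b_factor"])
    try:
        if fmt == "pdb":
            f = _pdb.PDBFile.read(str(path))
            atoms = _pdb.get_structure(f, **kwargs)
        else:
            f = _pdbx.CIFFile.read(str(path))
            atoms = _pdbx.get_structure(f, **kwargs)
    except Exception as exc:  # normalize parser failures
        if "0 models" in str(exc):
            raise EmptyStructureError(f"{path} contains no atoms") from exc
        raise StructureParseError(
            f"could not parse {path} as {fmt}: {exc}") from exc

    atoms = _filter_altlocs(atoms)
    if entry_id is None:
        entry_id = path.stem.upper()
    return StructureModel(atoms=atoms, entry_id=entry_id)


def extract_porphyrin_cores(model: StructureModel,
                            heme_names: tuple[str, ...] = DEFAULT_HEME_NAMES
                            ) -> list[PorphyrinCore]:
    """Extract one canonically ordered :class:`PorphyrinCore` per heme group.

    Heme residues are recognized by name (configurable whitelist); a heme
    with a missing macrocycle atom, a malformed ring or without a unique
    iron near the nitrogen centroid is skipped with a logged warning.
    Hydrogens are ignored.  Cores are sorted by (chain, residue number) and
    the result is independent of the input atom-record order.
    """
    atoms = model.atoms
    heavy = atoms[atoms.element != "H"]
    is_heme = np.isin(heavy.res_name, heme_names)
    heme_atoms = heavy[is_heme]

    fe_all = heavy[heavy.element == "FE"]

    groups = sorted({(c, int(r)) for c, r in
                     zip(heme_atoms.chain_id, heme_atoms.res_id)})
    cores: list[PorphyrinCore] = []
    for chain, res_id in groups:
        sel = heme_atoms[(heme_atoms.chain_id == chain)
                         & (heme_atoms.res_id == res_id)]
        name_to_xyz: dict[str, np.ndarray] = {}
        for i in range(sel.array_length()):
            name_to_xyz.setdefault(sel.atom_name[i].strip(), sel.coord[i])
        missing = [n for n in CANONICAL_ATOMS if n not in name_to_xyz]
        if missing:
            logger.warning("heme %s/%s in %s: missing macrocycle atom(s) %s; "
                           "skipped", chain, res_id, model.entry_id,
                           ",".join(missing))
            continue
        coords = np.array([name_to_xyz[n] for n in CANONICAL_ATOMS])
        ok, why = _is_macrocycle(coords)
        if not ok:
            logger.warning("heme %s/%s in %s: %s; skipped",
                           chain, res_id, model.entry_id, why)
            continue
        centroid = coords[[ATOM_INDEX[n] for n in NITROGEN_ATOMS]].mean(axis=0)
        fe_near = [fe_all.coord[i] for i in range(fe_all.array_length())
                   if np.linalg.norm(fe_all.coord[i] - centroid) <= 2.5]
        if len(fe_near) != 1:
            logger.warning("heme %s/%s in %s: %d Fe atoms within 2.5 A of the "
                           "N centroid (need exactly 1); skipped",
                           chain, res_id, model.entry_id, len(fe_near))
            continue
        res_name = str(sel.res_name[0])
        cores.append(PorphyrinCore(
            core_coords=coords, fe_coord=np.asarray(fe_near[0]),
            chain_id=str(chain), res_name=res_name, res_id=res_id,
            entry_id=model.entry_id))
    return cores
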