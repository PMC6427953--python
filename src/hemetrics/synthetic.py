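"""Synthetic fixtures: distorted porphyrins as PDB files, toy sequence sets
and melting curves with known ground-truth parameters.

Everything the analysis pipeline consumes can be generated here without any
network access, with every source of randomness driven by an explicit seed.
The porphyrin generator injects known amounts of the six out-of-plane modes
(amplitudes of order 0-1 Angstrom, the range seen in real heme proteins)
plus optional iid Gaussian coordinate noise, and can decorate the site with
an axial water oxygen at a chosen Fe distance and/or a lysine NZ
pseudo-atom at a chosen distance from a named meso carbon -- enough to
emulate a six-coordinate, cross-linked P460-type site or a vacant
five-coordinate c'-type site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import biotite.structure as struc
from biotite.structure.io import pdb as _pdb

from .melting import MeltCurve, melt_model
from .nsd import MODE_LABELS, build_minimal_basis
from .reference import CANONICAL_ATOMS, reference_coordinates
from .structure import PorphyrinCore


@dataclass(frozen=True)
class DistortionSpec:
    """Out-of-plane mode amplitudes plus noise and optional site decorations.

    ``amplitudes`` maps mode labels (``sad``, ``ruf``, ``dom``, ``wav_x``,
    ``wav_y``, ``pro``) to signed amplitudes in Angstrom.  ``noise_sigma``
    is the standard deviation of iid Gaussian noise added to every
    coordinate component.  ``axial_o_distance`` places a water oxygen on
    the +z axis at that distance from the iron; ``lys_nz`` places a lysine
    NZ pseudo-atom at ``(meso_label, distance)``, along the outward radial
    direction from that meso carbon.
    """

    amplitudes: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0
    axial_o_distance: float | None = None
    lys_nz: tuple[str, float] | None = None

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for k, v in self.amplitudes.items():
            if k not in MODE_LABELS:
                raise ValueError(f"unknown mode label {k!r}")
            if not np.isfinite(v):
                raise ValueError(f"amplitude for {k!r} not finite")


def make_reference_porphyrin() -> PorphyrinCore:
    """Planar, exactly D4h-symmetric macrocycle with Fe at the origin."""
    return PorphyrinCore(core_coords=reference_coordinates(),
                         fe_coord=np.zeros(3), chain_id="A",
                         res_name="HEM", res_id=1, entry_id="SYNTH")


def apply_distortion(ref: PorphyrinCore, spec: DistortionSpec) -> PorphyrinCore:
    """Displace a planar core along named modes; deterministic per seed."""
    basis = build_minimal_basis("group-theoretic")
    z = np.zeros(24)
    for label, amp in spec.amplitudes.items():
        z += amp * basis.vector(label)
    coords = np.array(ref.core_coords, dtype=float)
    coords[:, 2] += z
    fe = np.array(ref.fe_coord, dtype=float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    extra = []
    if spec.axial_o_distance is not None:
        o = fe + np.array([0.0, 0.0, spec.axial_o_distance])
        extra.append(("HOH", "O", "O", tuple(o)))
    if spec.lys_nz is not None:
        meso, dist = spec.lys_nz
        # anchor on the *distorted* meso position so the requested bond
        # distance is exact in the emitted fixture
        m = coords[CANONICAL_ATOMS.index(meso)]
        radial = m - fe
        radial /= np.linalg.norm(radial)
        nz = m + dist * radial
        extra.append(("LYS", "NZ", "N", tuple(nz)))

    return PorphyrinCore(core_coords=coords, fe_coord=fe,
                         chain_id=ref.chain_id, res_name=ref.res_name,
                         res_id=ref.res_id, entry_id=ref.entry_id,
                         extra_atoms=tuple(extra))


def write_fixture_pdb(core: PorphyrinCore, path) -> None:
    """Write a core (plus any decoration atoms) as a standard PDB file.

    The macrocycle and iron are emitted as HETATM records of one heme
    residue; decoration atoms become separate single-atom residues.  The
    output round-trips through :func:`hemetrics.structure.read_structure`
    at PDB coordinate precision (1e-3 Angstrom).
    """
    n_extra = len(core.extra_atoms)
    arr = struc.AtomArray(25 + n_extra)
    names = list(CANONICAL_ATOMS) + ["FE"]
    elements = [n[0] if not n.startswith("C") else "C" for n in CANONICAL_ATOMS]
    elements += ["FE"]
    coords = np.vstack([core.core_coords, core.fe_coord[None, :]])
    for i in range(25):
        arr.coord[i] = coords[i]
    arr.chain_id[:25] = core.chain_id
    arr.res_id[:25] = core.res_id
    arr.res_name[:25] = core.res_name
    arr.atom_name[:25] = names
    arr.element[:25] = elements
    for j, (res_name, atom_name, element, xyz) in enumerate(core.extra_atoms):
        i = 25 + j
        arr.coord[i] = xyz
        arr.chain_id[i] = core.chain_id
        arr.res_id[i] = core.res_id + 1 + j
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = element
    arr.hetero[:] = True
    arr.set_annotation("occupancy", np.ones(arr.array_length()))
    arr.set_annotation("b_factor", np.zeros(arr.array_length()))
    f = _pdb.PDBFile()
    _pdb.set_structure(f, arr)
    f.write(str(path))


@dataclass(frozen=True)
class MeltSpec:
    """Ground truth for a synthetic one- or two-transition melting curve.

    ``transitions`` is a sequence of (Tm in Celsius, van 't Hoff enthalpy
    in kJ/mol); ``baselines`` gives (intercept, slope) for the native,
    (optionally intermediate,) and denatured states in curve order.
    ``noise_sigma`` is additive Gaussian noise in ellipticity units.
    """

    transitions: tuple = ((58.4, 300.0),)
    baselines: tuple = ((-20.0, 0.01), (-2.0, -0.01))
    noise_sigma: float = 0.0
    t_min: float = 25.0
    t_max: float = 120.0
    t_step: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.t_step <= 0 or self.t_max <= self.t_min:
            raise ValueError("temperature grid must be strictly increasing")
        n = len(self.transitions)
        if n not in (1, 2):
            raise ValueError("1 or 2 transitions supported")
        if len(self.baselines) != n + 1:
            raise ValueError("need one baseline per state (n_transitions + 1)")
        for tm, dh in self.transitions:
            if not (self.t_min < tm < self.t_max):
                raise ValueError(f"Tm {tm} outside temperature grid")
            if dh <= 0:
                raise ValueError("van 't Hoff enthalpy must be positive")

    @property
    def temperatures(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1e-9, self.t_step)


def make_melt_curve(spec: MeltSpec) -> MeltCurve:
    """Generate a melting curve from the same model family the fitter assumes."""
    t = spec.temperatures
    tms = [tr[0] for tr in spec.transitions]
    dhs = [tr[1] for tr in spec.transitions]
    params = []
    for b in spec.baselines:
        params += list(b)
    for tm, dh in zip(tms, dhs):
        params += [tm, dh]
    theta = melt_model(t, len(spec.transitions), np.array(params))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        theta = theta + rng.normal(0.0, spec.noise_sigma, size=theta.shape)
    return MeltCurve(temperature=t, ellipticity=theta)
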