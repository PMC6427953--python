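"""Normal-coordinate structural decomposition (NSD) of heme out-of-plane distortion.

A porphyrin macrocycle extracted from a crystal structure is rarely planar.
NSD expresses its out-of-plane deformation as signed amplitudes along the
six lowest-frequency out-of-plane normal modes of the ideal D4h-symmetric
macrocycle -- the *minimal basis*, one mode per out-of-plane symmetry
species:

    ========  ========  ==========================================
    mode      symmetry  qualitative shape
    ========  ========  ==========================================
    sad       B2u       saddling: beta-carbon pairs alternate up/down
    ruf       B1u       ruffling: meso carbons alternate, pyrroles twist
    dom       A2u       doming: nitrogens pyramidalize toward the axial site
    wav_x     Eg        waving: single nodal line (x component)
    wav_y     Eg        waving: single nodal line (y component)
    pro       A1u       propellering: all pyrroles twist with one handedness
    ========  ========  ==========================================

The decomposition is a three-step pipeline:

1. :func:`build_minimal_basis` -- six orthonormal 24-vectors of z-weights in
   canonical atom order.
2. :func:`align_to_mean_plane` -- rigid-body alignment of the observed core
   to its least-squares mean plane, yielding 24 out-of-plane scalars.
3. :func:`nsd_decompose` -- orthonormal projection of the displacement
   field onto the basis, which for an orthonormal basis coincides with the
   least-squares fit.

Amplitude signs are convention-relative (fixed by requiring the reference
weight of NA in dom, CHA in ruf and C2A in sad to be positive); reports
carry signs, comparative plots conventionally use magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import (
    ATOM_CLASS,
    ATOM_INDEX,
    CANONICAL_ATOMS,
    reference_polar,
)
from .structure import PorphyrinCore

MODE_LABELS: tuple[str, ...] = ("sad", "ruf", "dom", "wav_x", "wav_y", "pro")
MODE_SYMMETRY: dict[str, str] = {
    "sad": "B2u", "ruf": "B1u", "dom": "A2u",
    "wav_x": "Eg", "wav_y": "Eg", "pro": "A1u",
}

# sign convention: (mode, canonical atom whose weight must be positive)
_SIGN_ANCHOR = {
    "sad": "C2A", "ruf": "CHA", "dom": "NA",
    "wav_x": "NA", "wav_y": "NB", "pro": "C1A",
}

# qualitative per-class weights of the idealized mode shapes; see docs
_DOM_WEIGHT = {"N": 1.0, "CA": 0.55, "CB": 0.25, "CH": 0.45}
_SAD_WEIGHT = {"N": 0.0, "CA": 0.6, "CB": 1.0, "CH": 0.0}
_PRO_WEIGHT = {"C1": 1.0, "C2": 0.6, "C3": -0.6, "C4": -1.0}


#: minimum |Fe out-of-plane offset| (Angstrom) for the Fe-displacement
#: z-sign rule; below this, coordinate noise would make the sign arbitrary,
#: so the deterministic handedness fallback is used instead
FE_OOP_SIGN_THRESHOLD = 0.05


class BasisError(ValueError):
    """Unknown basis source or malformed basis."""


class AlignmentError(ValueError):
    """Degenerate coordinates: mean plane undefined."""


@dataclass(frozen=True)
class ModeBasis:
    """Six orthonormal out-of-plane displacement vectors in canonical order."""

    vectors: np.ndarray          # (6, 24), rows ordered as MODE_LABELS
    labels: tuple[str, ...] = MODE_LABELS
    provenance: str = "group-theoretic"

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (6, 24):
            raise BasisError(f"expected (6, 24) vectors, got {v.shape}")
        gram = v @ v.T
        if not np.allclose(gram, np.eye(6), atol=1e-10):
            raise BasisError("mode vectors are not orthonormal to 1e-10")
        object.__setattr__(self, "vectors", v)

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[self.labels.index(label)]


def _raw_mode_patterns() -> dict[str, np.ndarray]:
    """Symmetry-adapted z-weight patterns prior to orthonormalization."""
    _, phi = reference_polar()
    cls = np.array(ATOM_CLASS)
    pat: dict[str, np.ndarray] = {}

    pat["sad"] = np.array([_SAD_WEIGHT[c] for c in cls]) * np.cos(2 * phi)
    pat["ruf"] = np.sin(2 * phi)
    pat["dom"] = np.array([_DOM_WEIGHT[c] for c in cls])
    pat["wav_x"] = np.cos(phi)
    pat["wav_y"] = np.sin(phi)

    pro = np.zeros(24)
    for name, w in _PRO_WEIGHT.items():
        for ring in "ABCD":
            pro[ATOM_INDEX[name + ring]] = w
    pat["pro"] = pro
    return pat


def _rigid_body_null_space() -> np.ndarray:
    """Orthonormal z-displacement patterns of rigid-body motions.

    A uniform z translation and the two mean-plane tilts produce apparent
    out-of-plane fields (1, x_i, y_i) that the mean-plane alignment
    removes; genuine deformation modes must be orthogonal to them, exactly
    as vibrational eigenvectors are orthogonal to rigid-body motions.
    """
    from .reference import reference_coordinates

    xyz = reference_coordinates()
    raw = np.vstack([np.ones(24), xyz[:, 0], xyz[:, 1]])
    q, _ = np.linalg.qr(raw.T)
    return q.T


def _orthonormalize(patterns: dict[str, np.ndarray]) -> np.ndarray:
    null = _rigid_body_null_space()
    vecs = []
    for label in MODE_LABELS:
        v = patterns[label].astype(float).copy()
        for u in null:
            v -= (u @ v) * u
        for u in vecs:
            v -= (u @ v) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-8:
            raise BasisError(f"mode {label} degenerate after Gram-Schmidt")
        v /= nrm
        anchor = ATOM_INDEX[_SIGN_ANCHOR[label]]
        if v[anchor] < 0:
            v = -v
        vecs.append(v)
    return np.array(vecs)


def build_minimal_basis(source: str = "static-table") -> ModeBasis:
    """Construct the six-mode minimal out-of-plane basis.

    Parameters
    ----------
    source:
        ``"static-table"`` loads the frozen idealized mode table shipped as
        package data; ``"group-theoretic"`` rebuilds the symmetry-adapted
        patterns by D4h projection and Gram-Schmidt orthonormalization.
        The two agree to high overlap; the static table guards against
        accidental drift of the constructive code path.
    """
    if source == "group-theoretic":
        return ModeBasis(_orthonormalize(_raw_mode_patterns()),
                         provenance="group-theoretic")
    if source == "static-table":
        from ._mode_table import STATIC_MODE_TABLE
        return ModeBasis(np.array(STATIC_MODE_TABLE), provenance="static-table")
    raise BasisError(f"unknown basis source {source!r}")


def build_extended_basis(source: str = "static-table"):
    """Two-modes-per-symmetry extended basis (not implemented).

    The comparative analysis this package supports uses the minimal basis
    only; the extended variant of the NSD literature is deliberately left
    as a stub.
    """
    raise NotImplementedError("extended NSD basis is not implemented; "
                              "use build_minimal_basis()")


@dataclass(frozen=True)
class AlignedCore:
    """A porphyrin core after mean-plane alignment.

    ``coords`` are the 24 canonical atoms with centroid at the origin and
    z along the mean-plane normal; ``aligned = rotation @ (x - translation)``
    reproduces them from the input coordinates.
    """

    coords: np.ndarray            # (24, 3)
    fe_coord: np.ndarray          # (3,)
    rotation: np.ndarray          # (3, 3)
    translation: np.ndarray       # (3,)
    core: PorphyrinCore = field(repr=False, default=None)

    @property
    def z_disp(self) -> np.ndarray:
        """Out-of-plane displacement of each canonical atom (Angstrom)."""
        return self.coords[:, 2]

    @property
    def fe_oop(self) -> float:
        """Signed out-of-plane displacement of the iron (Angstrom)."""
        return float(self.fe_coord[2])


def align_to_mean_plane(core: PorphyrinCore,
                        proximal_coord: np.ndarray | None = None) -> AlignedCore:
    """Rigidly align a core to its least-squares mean plane.

    The mean plane is the plane through the centroid of the 24 macrocycle
    atoms normal to the smallest-eigenvalue direction of their coordinate
    covariance (the iron is excluded).  The z sign is chosen so that the
    Fe-to-proximal-ligand direction (if ``proximal_coord`` is given), or
    otherwise the Fe out-of-plane displacement, points along -z.  For a
    perfectly planar core with in-plane iron the sign falls back to the
    right-handed normal of the canonical NA -> NB circulation, which makes
    the convention deterministic.  An in-plane rotation then registers the
    four nitrogens against the reference (NA on +x).
    """
    x = np.asarray(core.core_coords, dtype=float)
    centroid = x.mean(axis=0)
    xc = x - centroid
    cov = xc.T @ xc / 24.0
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-8 * max(evals[2], 1e-12):
        raise AlignmentError("degenerate (collinear) coordinates: "
                             "mean plane undefined")
    normal = evecs[:, 0]

    fe_rel = np.asarray(core.fe_coord, dtype=float) - centroid
    if proximal_coord is not None:
        v = np.asarray(proximal_coord, dtype=float) - np.asarray(core.fe_coord)
        if normal @ v > 0:
            normal = -normal
    elif abs(normal @ fe_rel) > FE_OOP_SIGN_THRESHOLD:
        if normal @ fe_rel > 0:
            normal = -normal
    else:
        handed = np.cross(xc[ATOM_INDEX["NA"]], xc[ATOM_INDEX["NB"]])
        if normal @ handed < 0:
            normal = -normal

    # rotation taking `normal` to +z (stable even for normal ~ -z)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(normal @ z)
    if np.linalg.norm(v) < 1e-12:
        r_plane = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        r_plane = np.eye(3) + vx + vx @ vx / (1.0 + c)

    rotated = xc @ r_plane.T

    # in-plane registration of the four N against reference directions
    ref_dirs = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
    cur = rotated[[ATOM_INDEX[n] for n in ("NA", "NB", "NC", "ND")], :2]
    num = float(np.sum(cur[:, 0] * ref_dirs[:, 1] - cur[:, 1] * ref_dirs[:, 0]))
    den = float(np.sum(cur[:, 0] * ref_dirs[:, 0] + cur[:, 1] * ref_dirs[:, 1]))
    theta = np.arctan2(num, den)
    ct, st = np.cos(theta), np.sin(theta)
    r_z = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])

    rotation = r_z @ r_plane
    coords = xc @ rotation.T
    fe = rotation @ fe_rel
    return AlignedCore(coords=coords, fe_coord=fe, rotation=rotation,
                       translation=centroid, core=core)


@dataclass(frozen=True)
class NSDResult:
    """Signed minimal-basis mode amplitudes for one heme core.

    ``d_oop_min`` is the root-sum-square of the six amplitudes (the
    distortion captured by the minimal basis); ``d_oop_total`` the
    root-sum-square of all 24 out-of-plane displacements; ``residual``
    the part of the distortion outside the minimal basis.
    """

    amplitudes: np.ndarray        # (6,), ordered as MODE_LABELS
    d_oop_min: float
    d_oop_total: float
    residual: float
    entry_id: str = ""
    chain_id: str = ""
    res_id: int = 0
    basis_provenance: str = ""

    def __getattr__(self, name):
        # d_sad, d_ruf, d_dom, d_wavx, d_wavy, d_pro accessors
        key = name.removeprefix("d_")
        lookup = {"wavx": "wav_x", "wavy": "wav_y"}.get(key, key)
        if name.startswith("d_") and lookup in MODE_LABELS:
            return float(self.amplitudes[MODE_LABELS.index(lookup)])
        raise AttributeError(name)

    def amplitude(self, label: str) -> float:
        return float(self.amplitudes[MODE_LABELS.index(label)])

    def as_dict(self) -> dict:
        d = {
            "entry": self.entry_id, "chain": self.chain_id,
            "res_id": self.res_id,
        }
        for lab, a in zip(MODE_LABELS, self.amplitudes):
            d[f"d_{lab.replace('_', '')}"] = float(a)
        d["d_oop_min"] = self.d_oop_min
        d["d_oop_total"] = self.d_oop_total
        d["residual"] = self.residual
        return d


def nsd_decompose(aligned: AlignedCore, basis: ModeBasis) -> NSDResult:
    """Project the out-of-plane displacement field onto the minimal basis.

    Because the basis is orthonormal the projection amplitudes equal the
    least-squares fit of all six modes simultaneously.
    """
    z = aligned.z_disp
    amps = basis.vectors @ z
    total = float(np.linalg.norm(z))
    dmin = float(np.linalg.norm(amps))
    # computed directly (not via sqrt(total^2 - dmin^2)) to avoid
    # catastrophic cancellation for near-pure minimal-basis distortions
    residual = float(np.linalg.norm(z - basis.vectors.T @ amps))
    core = aligned.core
    return NSDResult(
        amplitudes=amps, d_oop_min=dmin, d_oop_total=total, residual=residual,
        entry_id=getattr(core, "entry_id", ""),
        chain_id=getattr(core, "chain_id", ""),
        res_id=getattr(core, "res_id", 0),
        basis_provenance=basis.provenance,
    )


def decompose(core: PorphyrinCore, basis: ModeBasis | None = None,
              proximal_coord: np.ndarray | None = None) -> NSDResult:
    """Convenience: align a core and decompose it in one call."""
    if basis is None:
        basis = build_minimal_basis()
    return nsd_decompose(align_to_mean_plane(core, proximal_coord), basis)
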