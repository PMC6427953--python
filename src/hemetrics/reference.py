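"""Canonical porphyrin macrocycle definition and idealized D4h reference geometry.

The 24-atom macrocycle (4 pyrrole N, 16 pyrrole C, 4 meso C) is stored in a
fixed canonical order that traverses the ring one pyrrole quadrant at a time:

    NA, C1A, C2A, C3A, C4A, CHB,  NB, C1B, ... C4D, CHA

Atom names follow PDB heme nomenclature (HEM/HEC components): ``NA``-``ND``
are the pyrrole nitrogens, ``C1x``-``C4x`` the pyrrole carbons (C1/C4 are the
alpha carbons, C2/C3 the beta carbons) and ``CHA``-``CHD`` the meso bridge
carbons.  ``CHB`` bridges rings A and B, ..., ``CHA`` bridges D back to A,
closing the macrocycle.

The idealized D4h reference geometry places the iron at the origin with the
ring in the z = 0 plane, pyrrole A centred on the +x axis.  The radial orbit
parameters are solved once (cached) from canonical porphine bond lengths;
only the relative geometry matters for the normal-coordinate analysis.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

#: canonical atom order (see module docstring)
CANONICAL_ATOMS: tuple[str, ...] = (
    "NA", "C1A", "C2A", "C3A", "C4A", "CHB",
    "NB", "C1B", "C2B", "C3B", "C4B", "CHC",
    "NC", "C1C", "C2C", "C3C", "C4C", "CHD",
    "ND", "C1D", "C2D", "C3D", "C4D", "CHA",
)

#: the four meso (bridge) carbons in PDB nomenclature
MESO_ATOMS: tuple[str, ...] = ("CHA", "CHB", "CHC", "CHD")

#: the four pyrrole nitrogens
NITROGEN_ATOMS: tuple[str, ...] = ("NA", "NB", "NC", "ND")

# atom class by position within each 6-atom quadrant:
# N (pyrrole nitrogen), CA (alpha carbon), CB (beta carbon), CH (meso carbon)
_QUADRANT_CLASS = ("N", "CA", "CB", "CB", "CA", "CH")

#: chemical class of each canonical atom
ATOM_CLASS: tuple[str, ...] = tuple(_QUADRANT_CLASS[i % 6] for i in range(24))

#: index of each canonical atom name
ATOM_INDEX: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_ATOMS)}

# target bond lengths (Angstrom); canonical porphine/metalloporphyrin values
BOND_FE_N = 2.010
BOND_N_CA = 1.380
BOND_CA_CB = 1.440
BOND_CB_CB = 1.355
BOND_CA_CH = 1.395
ANGLE_CA_N_CA = 105.7  # pyrrole interior angle at N, degrees


def macrocycle_bonds() -> list[tuple[int, int]]:
    """The 28 covalent bonds of the macrocycle as canonical index pairs.

    Per quadrant: N-C1, C1-C2, C2-C3, C3-C4, C4-N, C4-CH, and CH-C1 of the
    following quadrant.  The meso carbons bond only to alpha carbons, never
    to the nitrogens.
    """
    bonds = []
    for p in range(4):
        o = 6 * p
        nxt = 6 * ((p + 1) % 4)
        bonds += [
            (o, o + 1), (o + 1, o + 2), (o + 2, o + 3), (o + 3, o + 4),
            (o + 4, o), (o + 4, o + 5), (o + 5, nxt + 1),
        ]
    return bonds


def canonical_angles() -> np.ndarray:
    """Angular position (radians) of each canonical atom around the ring.

    Pyrrole A is centred at 0, B at 90 deg, etc.; within quadrant p the
    atoms sit at base - phi_a (C1), base - phi_b (C2), base + phi_b (C3),
    base + phi_a (C4); the meso carbon at base + 45 deg.
    """
    _, phi = reference_polar()
    return phi


@lru_cache(maxsize=1)
def _orbit_parameters() -> tuple[float, float, float, float, float]:
    """Solve (r_alpha, phi_alpha, r_beta, phi_beta, r_meso) from bond targets."""

    def polar(r, a):
        return np.array([r * np.cos(a), r * np.sin(a)])

    def residuals(x):
        ra, pa, rb, pb, rm = x
        n = polar(BOND_FE_N, 0.0)
        c1 = polar(ra, -pa)
        c2 = polar(rb, -pb)
        c3 = polar(rb, pb)
        c4 = polar(ra, pa)
        ch = polar(rm, np.pi / 4)
        v1, v4 = c1 - n, c4 - n
        cosang = v1 @ v4 / (np.linalg.norm(v1) * np.linalg.norm(v4))
        return [
            np.linalg.norm(n - c1) - BOND_N_CA,
            np.linalg.norm(c1 - c2) - BOND_CA_CB,
            np.linalg.norm(c2 - c3) - BOND_CB_CB,
            np.linalg.norm(c4 - ch) - BOND_CA_CH,
            np.degrees(np.arccos(np.clip(cosang, -1, 1))) - ANGLE_CA_N_CA,
        ]

    x0 = (3.06, np.radians(20.0), 4.28, np.radians(9.0), 3.42)
    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise RuntimeError("reference geometry solve failed")
    return tuple(float(v) for v in sol.x)


@lru_cache(maxsize=1)
def reference_polar() -> tuple[np.ndarray, np.ndarray]:
    """(radii, angles) of the 24 canonical atoms in the D4h reference."""
    ra, pa, rb, pb, rm = _orbit_parameters()
    radii, angles = [], []
    for p in range(4):
        base = p * np.pi / 2
        radii += [BOND_FE_N, ra, rb, rb, ra, rm]
        angles += [base, base - pa, base - pb, base + pb, base + pa,
                   base + np.pi / 4]
    return np.asarray(radii), np.asarray(angles)


def reference_coordinates() -> np.ndarray:
    """24 x 3 Cartesian coordinates of the planar D4h reference (Fe at origin)."""
    r, phi = reference_polar()
    xyz = np.zeros((24, 3))
    xyz[:, 0] = r * np.cos(phi)
    xyz[:, 1] = r * np.sin(phi)
    return xyz
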