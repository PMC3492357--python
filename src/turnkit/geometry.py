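"""Backbone vector geometry: dihedrals, internal-to-Cartesian placement,
and the Kabsch–Sander hydrogen-bond energy.

All coordinates are in Ångström, all angles in degrees, energies in
kcal/mol.  These primitives underpin both the turn detectors (which need
H-bond energies and Cα distances) and the synthetic peptide builder
(which needs exact placement from φ/ψ/ω internal coordinates).
"""

from __future__ import annotations

import numpy as np

# Ideal backbone covalent geometry (Engh & Huber values, rounded).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8

# Kabsch–Sander electrostatic model: partial charges 0.42e / 0.20e and the
# dimensional factor 332 give 0.084 * 332 = 27.888 kcal/mol·Å.
KS_COUPLING = 0.084 * 332.0
#: Energies below this (kcal/mol) count as a hydrogen bond.
DEFAULT_HBOND_CUTOFF = -0.5
#: Any pair of interacting atoms closer than this is degenerate geometry.
MIN_ATOM_SEPARATION = 0.5


class DegenerateGeometryError(ValueError):
    """Raised when interacting atoms are (near-)coincident."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in degrees, IUPAC sign convention."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u = _unit(a - b)
    v = _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C with bond C-D of `length`, angle B-C-D
    of `angle` degrees and dihedral A-B-C-D of `torsion` degrees (NeRF).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            -length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def synthesize_amide_h(c_prev, n, ca) -> np.ndarray:
    """Backbone amide hydrogen position, 1.0 Å from N along the bisector
    of the C(i-1)–N and CA–N bond directions (pointing away from both).

    The first residue of a chain has no preceding carbonyl carbon and
    therefore no synthesizable donor hydrogen.
    """
    c_prev, n, ca = (np.asarray(x, dtype=float) for x in (c_prev, n, ca))
    u = _unit(n - c_prev)
    v = _unit(n - ca)
    return n + _unit(u + v) * 1.0


def hbond_energy(donor_n, donor_h, acceptor_o, acceptor_c) -> float:
    """Kabsch–Sander electrostatic hydrogen-bond energy in kcal/mol.

    ``E = 0.084 * 332 * (1/d(ON) + 1/d(CH) - 1/d(OH) - 1/d(CN))``

    for donor N-H and acceptor C=O.  A bond is asserted when the energy
    falls below the cutoff (−0.5 kcal/mol by default).  Raises
    :class:`DegenerateGeometryError` if any interacting pair is closer
    than 0.5 Å.
    """
    n, h, o, c = (np.asarray(x, dtype=float) for x in
                  (donor_n, donor_h, acceptor_o, acceptor_c))
    if not (np.isfinite(n).all() and np.isfinite(h).all()
            and np.isfinite(o).all() and np.isfinite(c).all()):
        raise ValueError("non-finite coordinates in hbond_energy")
    d_on = np.linalg.norm(o - n)
    d_ch = np.linalg.norm(c - h)
    d_oh = np.linalg.norm(o - h)
    d_cn = np.linalg.norm(c - n)
    dists = np.array([d_on, d_ch, d_oh, d_cn])
    if (dists < MIN_ATOM_SEPARATION).any():
        raise DegenerateGeometryError(
            f"atoms closer than {MIN_ATOM_SEPARATION} Å in hbond_energy"
        )
    return float(KS_COUPLING * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn))
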