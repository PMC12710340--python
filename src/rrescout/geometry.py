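"""Idealized peptide-backbone construction.

Builds N/CA/C/O backbone coordinates from (phi, psi) torsion lists using
standard bond lengths and angles with a trans peptide bond (omega = 180 deg).
Used by the synthetic-structure generators and by the secondary-structure
tests; real structures are parsed, never built.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

# Engh & Huber-style backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

# Canonical torsion pairs for ideal elements
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-119.0, 113.0)
# Coil torsions chosen outside both the helical and the extended (beta)
# dihedral regions so linkers never masquerade as elements.
COIL_PHI_PSI_CYCLE = ((-85.0, -5.0), (-100.0, 5.0), (60.0, 40.0))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D so that |C-D|=bond, angle(B,C,D)=angle, dihedral(A,B,C,D)=torsion.

    Natural extension reference frame (NeRF) construction.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: Sequence[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Build backbone atoms for a chain from per-residue (phi, psi).

    phi of the first residue and psi of the last are undefined in a real
    chain; the supplied values are used only to seed/cap the geometry.
    Returns one dict per residue with keys N, CA, C, O.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        return []
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: trans to the next amide nitrogen (dihedral psi+180)
    for i, res in enumerate(residues):
        psi = phi_psi[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return residues


def torsions_for_elements(elements: Iterable[tuple[str, int]]) -> list[tuple[float, float]]:
    """Expand (kind, length) element tuples into per-residue torsions.

    kind is one of 'H' (helix), 'E' (strand), 'C' (coil).
    """
    out: list[tuple[float, float]] = []
    coil_i = 0
    for kind, length in elements:
        for _ in range(length):
            if kind == "H":
                out.append(HELIX_PHI_PSI)
            elif kind == "E":
                out.append(STRAND_PHI_PSI)
            elif kind == "C":
                out.append(COIL_PHI_PSI_CYCLE[coil_i % len(COIL_PHI_PSI_CYCLE)])
                coil_i += 1
            else:
                raise ValueError(f"unknown element kind {kind!r}")
    return out


def rigid_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply a proper rigid-body transform to an (n, 3) coordinate array."""
    return coords @ rotation.T + translation


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
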