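"""Peptide construction from internal coordinates.

Builds polypeptide coordinates residue-by-residue with ideal bond lengths
and angles (NeRF-style placement), given per-residue backbone dihedrals and
optional side-chain chi angles. Used by the synthetic-structure generator to
create idealized calcium-binding loops, helical/strand flanks and decoy
loops with known ground truth; not a general-purpose model builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import virtual_cbeta
from .structio import Atom, Residue

# Ideal backbone geometry (Engh-Huber-like values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Side-chain topology: atom -> (frame atoms, bond, angle, dihedral source).
# The dihedral source is either a chi index (int, 0-based) or (chi, offset).
# Residues not listed are built with a C-beta only (alanine-like), which is
# all the generator needs for filler positions.
_SC = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, (0, 0.0))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, (0, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, (0, -120.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, (0, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, (1, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, (1, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, (0, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, (1, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, (1, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, (0, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, (1, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, (2, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, (2, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, (0, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, (1, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, (2, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, (2, 180.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, (0, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, (1, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, (2, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, (3, 0.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, (0, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, (0, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, (1, 0.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, (0, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, (1, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, (1, 120.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, (0, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, (0, -122.0)),
    ],
}

DEFAULT_CHIS = {
    "SER": [-60.0], "THR": [-60.0],
    "ASP": [-70.0, -20.0], "ASN": [-70.0, -20.0],
    "GLU": [-65.0, -65.0, -10.0], "GLN": [-65.0, -65.0, -10.0],
    "LYS": [-65.0, 180.0, 180.0, 180.0],
    "ILE": [-60.0, 170.0], "LEU": [-60.0, 175.0], "VAL": [175.0],
}


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position atom d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            -bond * math.sin(ang) * math.sin(dih),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


@dataclass
class ResidueSpec:
    """Internal-coordinate description of one residue in a chain."""

    aa: str  # one-letter code
    phi: float
    psi: float
    omega: float = 180.0
    chis: list[float] | None = None


def build_peptide(
    specs: list[ResidueSpec],
    chain_id: str = "A",
    start_seq_num: int = 1,
) -> list[Residue]:
    """Build Residue objects with full heavy-atom coordinates.

    phi of the first residue is unused (no preceding carbonyl); psi of the
    last residue still orients its carbonyl oxygen.
    """
    if not specs:
        return []
    backbone: list[dict[str, np.ndarray]] = []
    # First residue: N at origin, CA on x-axis, C in the xy-plane.
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(specs)):
        prev = backbone[-1]
        n_i = place_atom(
            prev["N"], prev["CA"], prev["C"],
            BOND_C_N, ANGLE_CA_C_N, specs[i - 1].psi,
        )
        ca_i = place_atom(
            prev["CA"], prev["C"], n_i,
            BOND_N_CA, ANGLE_C_N_CA, specs[i].omega,
        )
        c_i = place_atom(
            prev["C"], n_i, ca_i,
            BOND_CA_C, ANGLE_N_CA_C, specs[i].phi,
        )
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues: list[Residue] = []
    for i, spec in enumerate(specs):
        bb = backbone[i]
        res_name = ONE_TO_THREE[spec.aa.upper()]
        # Carbonyl O: anti to the next N (dihedral N-CA-C-O = psi + 180).
        o = place_atom(
            bb["N"], bb["CA"], bb["C"], BOND_C_O, ANGLE_CA_C_O, spec.psi + 180.0
        )
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", o),
        ]
        coords: dict[str, np.ndarray] = {k: v for k, v in bb.items()}
        coords["O"] = o
        if res_name != "GLY":
            cb = virtual_cbeta(bb["N"], bb["CA"], bb["C"])
            atoms.append(Atom("CB", "C", cb))
            coords["CB"] = cb
            chis = spec.chis if spec.chis is not None else DEFAULT_CHIS.get(res_name, [])
            for name, frame, bond, angle_deg, (chi_idx, offset) in _SC.get(res_name, []):
                chi = chis[chi_idx] if chi_idx < len(chis) else 0.0
                pos = place_atom(
                    coords[frame[0]], coords[frame[1]], coords[frame[2]],
                    bond, angle_deg, chi + offset,
                )
                element = "O" if name.startswith("O") else (
                    "N" if name.startswith("N") else "C"
                )
                atoms.append(Atom(name, element, pos))
                coords[name] = pos
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=start_seq_num + i,
                icode="",
                res_name=res_name,
                atoms=atoms,
            )
        )
    return residues
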