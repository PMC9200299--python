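"""Chemical and antibody constants shared across the package.

Everything geometric here is *ideal* covalent geometry (bond lengths in
Angstroms, angles in degrees) of the kind used for internal-coordinate chain
building.  The side-chain topology table drives both synthetic structure
generation (NeRF placement) and chi-angle extraction, so the two are exact
inverses by construction.
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = [
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
]
ONE_TO_THREE = dict(zip(AA1, AA3))
THREE_TO_ONE = {t: o for o, t in ONE_TO_THREE.items()}
AA_INDEX = {a: i for i, a in enumerate(AA1)}

# Residues excluded from labels: no C-beta (pairwise dihedrals), no C-gamma or
# non-rotameric (side-chain dihedrals).
NO_CB = {"GLY"}
NO_CHI = {"GLY", "ALA", "PRO"}

# ---------------------------------------------------------------------------
# Backbone ideal internal coordinates (Engh & Huber-like values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.6
OMEGA_TRANS = 180.0
# Improper torsion C(prev)-N-CA-CB fixing the C-beta branch.
DIHEDRAL_N_C_CA_CB = 122.68

# ---------------------------------------------------------------------------
# Chi-angle atom quadruples (IUPAC / PDB convention).  chi_k is the torsion of
# the listed four atoms; the table also fixes how many chi angles each residue
# type has.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}
N_CHI = {res: len(v) for res, v in CHI_ATOMS.items()}
for _res in ("GLY", "ALA", "PRO"):
    N_CHI[_res] = 0
MAX_CHI = 5

# ---------------------------------------------------------------------------
# Side-chain topology for internal-coordinate building.  Each entry is
#   (atom, (p1, p2, p3), bond, angle, torsion)
# where the new atom is placed at distance `bond` from p1, with angle
# new-p1-p2 = `angle`, and torsion new-p1-p2-p3 = `torsion`.  A torsion of
# ("chi", k) is the residue's chi_k; ("chi+", k, off) is chi_k plus a fixed
# branch offset; a float is a fixed torsion (ring planarity etc.).
Torsion = float | tuple
SIDECHAIN_TOPOLOGY: dict[str, list[tuple[str, tuple[str, str, str], float, float, Torsion]]] = {
    "ALA": [],
    "SER": [("OG", ("CB", "CA", "N"), 1.417, 110.8, ("chi", 1))],
    "CYS": [("SG", ("CB", "CA", "N"), 1.808, 114.4, ("chi", 1))],
    "THR": [("OG1", ("CB", "CA", "N"), 1.433, 109.5, ("chi", 1)),
            ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi+", 1, -120.0))],
    "VAL": [("CG1", ("CB", "CA", "N"), 1.527, 110.7, ("chi", 1)),
            ("CG2", ("CB", "CA", "N"), 1.527, 110.7, ("chi+", 1, 122.0))],
    "ILE": [("CG1", ("CB", "CA", "N"), 1.530, 110.4, ("chi", 1)),
            ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi+", 1, -122.0)),
            ("CD1", ("CG1", "CB", "CA"), 1.513, 113.9, ("chi", 2))],
    "LEU": [("CG", ("CB", "CA", "N"), 1.530, 116.3, ("chi", 1)),
            ("CD1", ("CG", "CB", "CA"), 1.521, 110.7, ("chi", 2)),
            ("CD2", ("CG", "CB", "CA"), 1.521, 110.7, ("chi+", 2, 122.6))],
    "ASP": [("CG", ("CB", "CA", "N"), 1.516, 113.0, ("chi", 1)),
            ("OD1", ("CG", "CB", "CA"), 1.249, 118.5, ("chi", 2)),
            ("OD2", ("CG", "CB", "CA"), 1.249, 118.5, ("chi+", 2, 180.0))],
    "ASN": [("CG", ("CB", "CA", "N"), 1.516, 112.6, ("chi", 1)),
            ("OD1", ("CG", "CB", "CA"), 1.231, 120.8, ("chi", 2)),
            ("ND2", ("CG", "CB", "CA"), 1.328, 116.4, ("chi+", 2, 180.0))],
    "GLU": [("CG", ("CB", "CA", "N"), 1.530, 114.1, ("chi", 1)),
            ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2)),
            ("OE1", ("CD", "CG", "CB"), 1.249, 118.5, ("chi", 3)),
            ("OE2", ("CD", "CG", "CB"), 1.249, 118.5, ("chi+", 3, 180.0))],
    "GLN": [("CG", ("CB", "CA", "N"), 1.530, 114.1, ("chi", 1)),
            ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2)),
            ("OE1", ("CD", "CG", "CB"), 1.231, 120.8, ("chi", 3)),
            ("NE2", ("CD", "CG", "CB"), 1.328, 116.4, ("chi+", 3, 180.0))],
    "MET": [("CG", ("CB", "CA", "N"), 1.530, 114.1, ("chi", 1)),
            ("SD", ("CG", "CB", "CA"), 1.807, 112.7, ("chi", 2)),
            ("CE", ("SD", "CG", "CB"), 1.789, 100.8, ("chi", 3))],
    "LYS": [("CG", ("CB", "CA", "N"), 1.530, 114.1, ("chi", 1)),
            ("CD", ("CG", "CB", "CA"), 1.520, 111.3, ("chi", 2)),
            ("CE", ("CD", "CG", "CB"), 1.520, 111.3, ("chi", 3)),
            ("NZ", ("CE", "CD", "CG"), 1.489, 111.9, ("chi", 4))],
    "ARG": [("CG", ("CB", "CA", "N"), 1.530, 114.1, ("chi", 1)),
            ("CD", ("CG", "CB", "CA"), 1.520, 111.3, ("chi", 2)),
            ("NE", ("CD", "CG", "CB"), 1.461, 111.7, ("chi", 3)),
            ("CZ", ("NE", "CD", "CG"), 1.329, 124.6, ("chi", 4)),
            ("NH1", ("CZ", "NE", "CD"), 1.326, 120.0, ("chi", 5)),
            ("NH2", ("CZ", "NE", "CD"), 1.326, 120.0, ("chi+", 5, 180.0))],
    "HIS": [("CG", ("CB", "CA", "N"), 1.497, 113.7, ("chi", 1)),
            ("ND1", ("CG", "CB", "CA"), 1.380, 122.9, ("chi", 2)),
            ("CD2", ("CG", "CB", "CA"), 1.354, 129.7, ("chi+", 2, 180.0)),
            ("CE1", ("ND1", "CG", "CB"), 1.326, 109.0, 180.0),
            ("NE2", ("CD2", "CG", "CB"), 1.373, 107.0, 180.0)],
    "PHE": [("CG", ("CB", "CA", "N"), 1.502, 113.8, ("chi", 1)),
            ("CD1", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2)),
            ("CD2", ("CG", "CB", "CA"), 1.384, 120.8, ("chi+", 2, 180.0)),
            ("CE1", ("CD1", "CG", "CB"), 1.382, 120.8, 180.0),
            ("CE2", ("CD2", "CG", "CB"), 1.382, 120.8, 180.0),
            ("CZ", ("CE1", "CD1", "CG"), 1.382, 120.0, 0.0)],
    "TYR": [("CG", ("CB", "CA", "N"), 1.502, 113.8, ("chi", 1)),
            ("CD1", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2)),
            ("CD2", ("CG", "CB", "CA"), 1.384, 120.8, ("chi+", 2, 180.0)),
            ("CE1", ("CD1", "CG", "CB"), 1.382, 120.8, 180.0),
            ("CE2", ("CD2", "CG", "CB"), 1.382, 120.8, 180.0),
            ("CZ", ("CE1", "CD1", "CG"), 1.382, 120.0, 0.0),
            ("OH", ("CZ", "CE1", "CD1"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", ("CB", "CA", "N"), 1.498, 113.6, ("chi", 1)),
            ("CD1", ("CG", "CB", "CA"), 1.365, 126.9, ("chi", 2)),
            ("CD2", ("CG", "CB", "CA"), 1.433, 126.7, ("chi+", 2, 180.0)),
            ("NE1", ("CD1", "CG", "CB"), 1.374, 110.2, 180.0),
            ("CE2", ("CD2", "CG", "CB"), 1.409, 107.2, 180.0),
            ("CE3", ("CD2", "CG", "CB"), 1.398, 133.9, 0.0),
            ("CZ2", ("CE2", "CD2", "CG"), 1.394, 122.4, 180.0),
            ("CZ3", ("CE3", "CD2", "CG"), 1.382, 118.7, 180.0),
            ("CH2", ("CZ2", "CE2", "CD2"), 1.368, 117.5, 180.0)],
    # Proline's ring is non-rotameric; CG/CD are placed at fixed puckered
    # torsions (the ring is not closed back to N exactly -- a documented
    # idealization; chi angles are masked for PRO regardless).
    "PRO": [("CG", ("CB", "CA", "N"), 1.492, 104.5, 30.0),
            ("CD", ("CG", "CB", "CA"), 1.503, 106.1, -35.0)],
    "GLY": [],
}

SIDECHAIN_ATOMS = {res: [entry[0] for entry in topo]
                   for res, topo in SIDECHAIN_TOPOLOGY.items()}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


def heavy_atoms(res3: str) -> list[str]:
    """All heavy atoms of a residue type, backbone first."""
    atoms = list(BACKBONE_ATOMS)
    if res3 != "GLY":
        atoms.append("CB")
    atoms.extend(SIDECHAIN_ATOMS[res3])
    return atoms


def atom_element(name: str) -> str:
    """Element symbol from a PDB heavy-atom name (C/N/O/S for amino acids)."""
    return name.strip()[0]


# ---------------------------------------------------------------------------
# Chothia CDR windows (residue-number ranges, inclusive) on each chain.
CHOTHIA_CDRS: dict[str, tuple[str, int, int]] = {
    "CDR-H1": ("H", 26, 32),
    "CDR-H2": ("H", 52, 56),
    "CDR-H3": ("H", 95, 102),
    "CDR-L1": ("L", 24, 34),
    "CDR-L2": ("L", 50, 56),
    "CDR-L3": ("L", 89, 97),
}

# ---------------------------------------------------------------------------
# Maximum accessible surface areas (A^2) per residue, "theoretical" column of
# Tien et al. 2013, usable as an alternative normalization for relative SASA.
TIEN_THEORETICAL_MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
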