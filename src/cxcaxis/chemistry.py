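"""Residue-level chemistry tables for heavy-atom contact criteria.

The tables encode which protein heavy atoms can act as hydrogen-bond donors
or acceptors, which carry formal charge at physiological pH, and which
side-chain carbons count as apolar. Criteria are heavy-atom only (no explicit
hydrogens, no angle term), which is the appropriate level for frames
back-converted from coarse-grained simulations where hydrogen placement is
untrustworthy.
"""

from __future__ import annotations

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain N/O donors (heavy atoms bearing at least one hydrogen).
_SIDECHAIN_DONORS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"},
}

# Side-chain N/O acceptors (lone-pair bearing).
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

# Formal charges at pH 7.4.
ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
CATION_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}
# Histidine ring nitrogens count as cationic only when the analysis is run
# with charged His enabled.
HIS_RING_N = {"ND1", "NE2"}

# Residues whose side chains are apolar; their side-chain carbons enter the
# hydrophobic-contact criterion.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}

# Canonical side-chain heavy atoms per residue (used by selections).
SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (protein conventions)."""
    name = atom_name.strip()
    if not name:
        return ""
    if name[:2].upper() in ("CL", "BR") and len(name) >= 2:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def is_hbond_donor(res_name: str, atom_name: str) -> bool:
    """Heavy-atom donor capability (backbone amide N plus the side-chain table)."""
    if atom_name == "N" and res_name != "PRO":
        return True
    return atom_name in _SIDECHAIN_DONORS.get(res_name, ())


def is_hbond_acceptor(res_name: str, atom_name: str) -> bool:
    """Heavy-atom acceptor capability (backbone carbonyl O plus the table)."""
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in _SIDECHAIN_ACCEPTORS.get(res_name, ())


def is_anion_atom(res_name: str, atom_name: str) -> bool:
    return atom_name in ANION_ATOMS.get(res_name, ())


def is_cation_atom(res_name: str, atom_name: str, his_charged: bool = False) -> bool:
    if atom_name in CATION_ATOMS.get(res_name, ()):
        return True
    return his_charged and res_name == "HIS" and atom_name in HIS_RING_N


def is_apolar_carbon(res_name: str, atom_name: str) -> bool:
    """Side-chain carbon of an apolar residue (hydrophobic criterion)."""
    if res_name not in APOLAR_RESIDUES:
        return False
    if atom_name in BACKBONE_ATOMS:
        return False
    return element_from_atom_name(atom_name) == "C"
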