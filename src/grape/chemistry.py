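"""Amino-acid chemistry tables used by the structure and feature modules.

All tables operate on heavy atoms only: hydrogens are discarded at parse
time, so hydrogen-bond geometry is expressed through donor heavy atoms and
their covalently bonded antecedents.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)
STANDARD_AA1 = frozenset(ONE_TO_THREE)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# Residues whose side chains participate in hydrophobic packing; only
# side-chain carbon atoms of these residues are counted as contact partners.
HYDROPHOBIC_AA1 = frozenset("AVLIMFWPY")

# Substitutions involving glycine or proline are flagged as potential
# backbone-conformational-entropy changes.
ENTROPY_AA1 = frozenset("GP")

# Side-chain hydrogen-bond donors: residue -> {donor atom: antecedent atom}.
# The antecedent is the heavy atom covalently bonded to the donor; the
# antecedent-donor-acceptor angle stands in for the D-H...A angle.
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
}

# Side-chain N/O hydrogen-bond acceptors per residue.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}


def donor_atoms(res_name3: str) -> dict[str, str]:
    """Map donor atom name -> antecedent atom name for one residue.

    Includes the backbone amide nitrogen (antecedent CA) for every residue
    except proline, whose ring nitrogen carries no hydrogen.
    """
    donors = dict(SIDECHAIN_DONORS.get(res_name3, {}))
    if res_name3 != "PRO":
        donors["N"] = "CA"
    return donors


def acceptor_atoms(res_name3: str) -> tuple[str, ...]:
    """Acceptor heavy-atom names for one residue (backbone carbonyl O plus
    side-chain N/O acceptors)."""
    return ("O",) + SIDECHAIN_ACCEPTORS.get(res_name3, ())
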