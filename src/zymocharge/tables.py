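"""Static residue-level reference tables.

Charge classes, hydroxyl (PTM-prone) residues and their replacement rules,
van der Waals radii, theoretical maximum solvent accessibilities, and
one/three-letter code conversions.  Everything downstream imports from here
so that conventions are defined exactly once.
"""

from __future__ import annotations

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Formal side-chain charge class at neutral-to-mildly-basic pH.
#: Asp/Glu carry -1, Lys/Arg +1; His is treated as neutral and terminal
#: charges are ignored.
CHARGE: dict[str, int] = {"D": -1, "E": -1, "K": +1, "R": +1}


def charge_of(residue: str) -> int:
    """Charge class of a one-letter residue code (-1, 0 or +1)."""
    return CHARGE.get(residue, 0)


#: Residues with side-chain hydroxyl groups, i.e. candidate sites for
#: O-linked post-translational modification (phosphorylation, glycosylation).
HYDROXYL_RESIDUES: frozenset[str] = frozenset("STY")

#: Replacement chosen when a proposed substitution would introduce a
#: hydroxyl-bearing residue: Thr -> Leu, Ser -> Ala, Tyr -> Asn.  The
#: replacements are charge-neutral and roughly isosteric.
PTM_SAFE_FALLBACK: dict[str, str] = {"T": "L", "S": "A", "Y": "N"}

#: Van der Waals radii in Angstrom (Bondi/Chothia-style heavy-atom values).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Theoretical maximum solvent accessibility (A^2) of residue X in an
#: extended Gly-X-Gly tripeptide (Tien-style table), used to normalise
#: absolute SASA into relative exposure.
MAX_ACCESSIBILITY: dict[str, float] = {
    "A": 129.0,
    "R": 274.0,
    "N": 195.0,
    "D": 193.0,
    "C": 167.0,
    "Q": 225.0,
    "E": 223.0,
    "G": 104.0,
    "H": 224.0,
    "I": 197.0,
    "L": 201.0,
    "K": 236.0,
    "M": 224.0,
    "F": 240.0,
    "P": 159.0,
    "S": 155.0,
    "T": 172.0,
    "W": 285.0,
    "Y": 263.0,
    "V": 174.0,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Representative side-chain atom carrying the formal charge of a charged
#: residue (C-alpha is used as fallback when the atom is absent).
CHARGE_BEARING_ATOM: dict[str, str] = {
    "ASP": "CG",
    "GLU": "CD",
    "LYS": "NZ",
    "ARG": "CZ",
}
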