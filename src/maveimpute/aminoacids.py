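"""Amino-acid alphabets, residue-code tables and physicochemical scales.

The physicochemical scales feed the imputation model's feature table:

* hydropathy — Kyte & Doolittle (1982) hydropathy index
* volume    — Zamyatnin (1972) residue volume, cubic angstroms
* charge    — formal side-chain charge at pH 7 (His treated as neutral,
  pKa ~6.0)
* polarity  — binary polar/nonpolar classification

BLOSUM62 is loaded from Biopython rather than re-packaged here.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

#: The 20 standard amino acids, one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Token used for translation-termination (stop / nonsense) substitutions.
STOP = "*"

#: Canonical token for synonymous (amino-acid-preserving) substitutions.
SYNONYMOUS = "="

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}

ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}

# Kyte & Doolittle hydropathy index.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Zamyatnin residue volumes (A^3).
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Formal side-chain charge at pH 7.
CHARGE = {aa: 0.0 for aa in AA_ALPHABET}
CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0})

# Binary polarity (1 = polar side chain).
_POLAR = set("RNDQEHKSTY")
POLARITY = {aa: (1.0 if aa in _POLAR else 0.0) for aa in AA_ALPHABET}

#: Ordered (name, table) pairs for the four physicochemical properties.
PROPERTY_SCALES = (
    ("hydropathy", HYDROPATHY),
    ("volume", VOLUME),
    ("charge", CHARGE),
    ("polarity", POLARITY),
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(wt: str, alt: str) -> int:
    """BLOSUM62 substitution score for ``wt`` -> ``alt`` (symmetric)."""
    return int(_BLOSUM62[wt, alt])
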