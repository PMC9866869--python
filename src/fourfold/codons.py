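"""Shared alphabets and codon indexing.

All sequences are handled on the DNA alphabet (T, not U). Codons are indexed
lexicographically over ``ACGT`` so that ``CODONS[0] == "AAA"`` and
``CODONS[63] == "TTT"``; every 64-vector and 64x64 matrix in the package uses
this order.
"""

from __future__ import annotations

import itertools

NUCLEOTIDES: str = "ACGT"
NUC_INDEX: dict[str, int] = {n: i for i, n in enumerate(NUCLEOTIDES)}

CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: canonical amino acids, alphabetical by 3-letter code
AMINO_ACIDS_3: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS_3)}

STOP = "Stop"
#: row/column index of the stop "residue" in the 21x21 acceptance matrix
STOP_INDEX = len(AMINO_ACIDS_3)

AA1_TO_AA3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}
AA3_TO_AA1: dict[str, str] = {v: k for k, v in AA1_TO_AA3.items()}


def third_position(codon: str) -> str:
    return codon[2]
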