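"""Standard genetic code helpers shared by the coding-potential and tRNA modules.

Sequences are stored as DNA; codon/anticodon pairing logic runs in the RNA
alphabet with explicit T<->U conversion at the boundary.
"""

from __future__ import annotations

from typing import Dict, List

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard code

#: stop codons, DNA alphabet
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

#: the 61 sense codons, DNA alphabet, lexicographic order
SENSE_CODONS = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set("ACGT"))
)

#: codon -> single-letter amino acid
CODON_TO_AA: Dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}
AA_ONE_LETTER = {v: k for k, v in AA_THREE_LETTER.items()}

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement in the DNA alphabet (U treated as T)."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def codon_amino_acid(codon: str) -> str:
    """Single-letter amino acid of a sense codon (DNA or RNA alphabet)."""
    codon = to_dna(codon)
    if codon not in CODON_TO_AA:
        raise ValueError(f"{codon!r} is not a sense codon")
    return CODON_TO_AA[codon]


def anticodon_amino_acid(anticodon: str) -> str:
    """Amino acid carried by a tRNA with this anticodon (via its WC codon)."""
    return codon_amino_acid(reverse_complement(anticodon))


def wc_codon(anticodon: str) -> str:
    """The Watson-Crick codon read by an anticodon (DNA alphabet)."""
    return reverse_complement(anticodon)


def sense_codons_rna() -> List[str]:
    return [to_rna(c) for c in SENSE_CODONS]
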