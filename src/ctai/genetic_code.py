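"""Standard genetic code helpers on the RNA alphabet.

All sequence handling in this package is RNA-uppercase internally; DNA input
(``T``) is accepted everywhere and normalized on entry. Tables come from
biopython's standard codon table.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

_RNA_TABLE = CodonTable.standard_rna_table

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_RNA_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_RNA_TABLE.stop_codons)

SENSE_CODONS: frozenset[str] = frozenset(CODON_TO_AA)

RNA_BASES = frozenset("ACGU")

#: Watson:Crick partners, codon third base -> anticodon first (position 34) base
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA ``T`` to RNA ``U``; strip gaps and whitespace."""
    return seq.upper().replace("T", "U").translate({ord(c): None for c in " \t\r\n-"})


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; raises on stops and junk."""
    codon = normalize_rna(codon)
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no amino acid")
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not a codon: {codon!r}") from None


@lru_cache(maxsize=None)
def synonymous_codons(codon: str) -> frozenset[str]:
    """The synonymous family (standard code) containing *codon*, stops excluded."""
    aa = translate_codon(codon)
    return frozenset(c for c, a in CODON_TO_AA.items() if a == aa)


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codons (RNA-normalized)."""
    seq = normalize_rna(seq)
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
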