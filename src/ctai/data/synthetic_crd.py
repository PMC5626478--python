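"""SYNTHETIC stand-in for the LARP4 coding-region determinant (CRD) and its
codon-swap (CS) construct series.

The real CRD nucleotide sequence and CS construct sequences are published only
as figures, with no machine-readable deposit, so this module constructs a
synthetic 72-codon region (full-length coordinates 287–358) that satisfies
every published constraint on the real one:

* 33 of the 61 sense codons occur in the region;
* 30/72 = 42% of codons are strictly bin-1-cognate (every decoding anticodon
  in the lowest-abundance quartile of the measured HEK293 pool), arranged in
  clusters of consecutive bin-1 codons;
* 7 Tyr codons of which 5 are wobble UAU; 5/5 Phe are UUU; 5/5 Asn are AAU
  (NNU:NNC ratios 5:2, 5:0, 5:0);
* CSb differs from WT by 14 third-position U→C swaps (10 of them at all-A/U
  weak codons), CSa adds the 5 Asn AAU→AAC swaps, CS-Tyr differs from CS-B by
  exactly the 7 Tyr U→C swaps, and CSc carries 13 Thr/Pro/Ile swaps that
  change the decoding anticodon;
* under default constraints the region ctAI scores order as
  CS-W < WT < CSc < CSb < CS-I < CSa < CS-R < CS-B < CS-Tyr.

It is a synthetic construction, not the LARP4 sequence: protein identity and
codon order are invented, only the codon-composition statistics above are
faithful.
"""

from __future__ import annotations

from ..scoring import OrfSequence, Region

#: 1-based codon coordinates of the region within the full-length ORF
CRD_SPAN = Region(287, 358)

#: the synthetic wild-type region, 72 codons, 5'->3'
WT_CODONS: tuple[str, ...] = (
    "CAU", "UAU", "ACA", "ACA", "CCA", "UUU", "AUA", "ACA", "AGC", "UUU",
    "AAU", "GCA", "CUG", "GAG", "AAA", "UAC", "CCG", "CCC", "AUA", "CAA",
    "UUU", "UAU", "ACG", "AGC", "AAU", "GGA", "GUG", "AAG", "CUG", "UCA",
    "CAU", "UAU", "CCA", "ACA", "AUC", "UUU", "AGC", "AAU", "GAU", "AGA",
    "GGG", "GAA", "CUA", "UGG", "AAG", "UAU", "CCG", "CCC", "AUA", "ACG",
    "AGC", "UUU", "AAU", "GUG", "GCA", "GAG", "AAA", "UAC", "ACC", "AUC",
    "CAA", "AGC", "UAU", "AAU", "UGU", "CGG", "GGA", "GAA", "AGA", "CUG",
    "UUG", "AUG",
)

_UUC = {k: "UUC" for k in (6, 10, 21, 36, 52)}       # Phe UUU -> UUC
_UAC = {k: "UAC" for k in (2, 22, 32, 46, 63)}       # Tyr UAU -> UAC
_AAC = {k: "AAC" for k in (11, 25, 38, 53, 64)}      # Asn AAU -> AAC
_OTHER_UC = {1: "CAC", 31: "CAC", 39: "GAC", 65: "UGC"}  # His/Asp/Cys NNU -> NNC
_ACU = {k: "ACU" for k in (3, 4, 8, 34)}             # Thr ACA -> ACU
_ACGU = {k: "ACU" for k in (23, 50)}                 # Thr ACG -> ACU
_CCU = {k: "CCU" for k in (18, 48)}                  # Pro CCC -> CCU
_AUU = {k: "AUU" for k in (7, 19, 49)}               # Ile AUA -> AUU

#: per-variant swap tables, 1-based region-local codon index -> new codon
VARIANT_SWAPS: dict[str, dict[int, str]] = {
    "WT": {},
    # deoptimized: direct->wobble Tyr swaps plus Thr swaps onto the scarcest anticodon
    "CS-W": {16: "UAU", 58: "UAU", 23: "ACA", 50: "ACA", 59: "ACA"},
    # 13 Thr/Pro/Ile swaps that change the decoding anticodon set
    "CSc": {**_ACU, **_ACGU, 59: "ACU", 18: "CCA", 48: "CCA", **_AUU, 5: "CCU"},
    # 14 same-anticodon U->C wobble swaps, Asn codons untouched
    "CSb": {**_UUC, **_UAC, **_OTHER_UC},
    # CSb plus the 5 Asn AAU->AAC swaps
    "CSa": {**_UUC, **_UAC, **_OTHER_UC, **_AAC},
    # mixture: weak-codon U->C swaps plus Thr/Pro different-anticodon swaps
    "CS-I": {**_UUC, **_UAC, **_ACU, **_CCU},
    # CSa plus Thr ACA->ACU different-anticodon swaps
    "CS-R": {**_UUC, **_UAC, **_OTHER_UC, **_AAC, **_ACU},
    # broadly optimized, but all 7 Tyr held at wobble UAU
    "CS-B": {
        **_UUC, **_AAC, **_OTHER_UC, 16: "UAU", 58: "UAU",
        **_ACU, **_ACGU, 59: "ACU", **_CCU, **_AUU, 35: "AUU", 60: "AUU",
        20: "CAG", 61: "CAG", 9: "UCA", 24: "UCA", 37: "UCA", 51: "UCA",
        62: "UCA", 42: "GAG", 68: "GAG", 15: "AAG", 57: "AAG",
    },
}
# CS-B with all 7 Tyr codons taken to direct-pairing UAC
VARIANT_SWAPS["CS-Tyr"] = {
    **VARIANT_SWAPS["CS-B"], **_UAC, 16: "UAC", 58: "UAC",
}

#: the Table-2 region ctAI ordering these constructs reproduce (ascending)
EXPECTED_CTAI_ORDER = (
    "CS-W", "WT", "CSc", "CSb", "CS-I", "CSa", "CS-R", "CS-B", "CS-Tyr",
)


def crd_constructs() -> dict[str, OrfSequence]:
    """The synthetic CRD construct series as standalone 72-codon ORFs."""
    wt = OrfSequence(id="WT", codons=WT_CODONS)
    out = {}
    for name, swaps in VARIANT_SWAPS.items():
        out[name] = wt.with_codons(swaps, id=name)
    return out


def crd_region() -> Region:
    """The region span in construct-local coordinates (the whole 72 codons)."""
    return Region(1, len(WT_CODONS))
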