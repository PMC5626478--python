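"""Synonymous codon-swap variant design and region codon-bias statistics.

Variant design operates codon-by-codon: because the ctAI statistic is a
geometric mean of independent per-codon adaptiveness values, choosing the
best (or worst) synonym at each position is globally optimal — no
combinatorial search is needed. All designs preserve the protein sequence by
construction and touch only the stated region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from .adaptiveness import AdaptivenessTable
from .genetic_code import synonymous_codons, translate_codon
from .pool import BinPartition, DecodingMap
from .scoring import OrfSequence, Region, score_region

__all__ = [
    "Swap",
    "VariantDesign",
    "BiasReport",
    "wobble_pyrimidine_swap",
    "design_variant",
    "bias_statistics",
    "diff_codons",
]


@dataclass(frozen=True)
class Swap:
    """One synonymous codon replacement at a 1-based codon index."""

    codon_index: int
    from_codon: str
    to_codon: str


@dataclass(frozen=True)
class VariantDesign:
    """A synonymous-swap variant of an ORF region."""

    source_orf_id: str
    region: Region
    swaps: tuple[Swap, ...]
    variant: OrfSequence
    objective: str
    predicted_ctai_region: float | None = None

    def __post_init__(self) -> None:
        for swap in self.swaps:
            if not self.region.start <= swap.codon_index <= self.region.end:
                raise ValueError(f"swap at {swap.codon_index} outside region")
            if translate_codon(swap.from_codon) != translate_codon(swap.to_codon):
                raise ValueError(
                    f"non-synonymous swap {swap.from_codon}->{swap.to_codon}"
                )


def diff_codons(a: OrfSequence, b: OrfSequence) -> list[Swap]:
    """Positions (1-based) where two equal-length ORFs differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return [
        Swap(k, ca, cb)
        for k, (ca, cb) in enumerate(zip(a.codons, b.codons), start=1)
        if ca != cb
    ]


def _apply(
    orf: OrfSequence, region: Region, swaps: list[Swap], objective: str, variant_id: str,
    table: AdaptivenessTable | None = None,
) -> VariantDesign:
    variant = orf.with_codons({s.codon_index: s.to_codon for s in swaps}, id=variant_id)
    predicted = None
    if table is not None:
        predicted = score_region(variant, region, table)
    return VariantDesign(
        source_orf_id=orf.id,
        region=region,
        swaps=tuple(swaps),
        variant=variant,
        objective=objective,
        predicted_ctai_region=predicted,
    )


def wobble_pyrimidine_swap(
    orf: OrfSequence,
    region: Region,
    decoding_map: DecodingMap,
    amino_acids: Iterable[str] | None = None,
    variant_id: str | None = None,
    table: AdaptivenessTable | None = None,
) -> VariantDesign:
    """Replace NNU codons in the region by their NNC synonyms where the same
    anticodon decodes both — converting wobble U:G (or U:I) pairing to a direct
    Watson:Crick match without changing which tRNA is used.

    *amino_acids* optionally restricts the swaps to a set of one-letter codes.
    """
    region.check_within(len(orf))
    aa_filter = {a.upper() for a in amino_acids} if amino_acids is not None else None
    swaps = []
    for k in region.codon_indices():
        codon = orf.codons[k - 1]
        if codon[2] != "U":
            continue
        partner = codon[:2] + "C"
        if partner not in synonymous_codons(codon):
            continue
        if aa_filter is not None and translate_codon(codon) not in aa_filter:
            continue
        if decoding_map.anticodons_for(codon) & decoding_map.anticodons_for(partner):
            swaps.append(Swap(k, codon, partner))
    return _apply(
        orf, region, swaps, "wobble-U-to-C", variant_id or f"{orf.id}_wobbleUC", table
    )


def design_variant(
    orf: OrfSequence,
    region: Region,
    table: AdaptivenessTable,
    objective: Literal["maximize", "minimize"],
    mode: Literal["any-synonym", "different-anticodon-only"] = "any-synonym",
    decoding_map: DecodingMap | None = None,
    variant_id: str | None = None,
) -> VariantDesign:
    """Greedy per-codon synonym choice toward max (or min) adaptiveness.

    ``different-anticodon-only`` restricts candidates to synonyms whose
    decoding anticodon set differs from the source codon's (requires
    *decoding_map*). Ties break toward the source codon, then
    lexicographically. Singleton families yield no swap.
    """
    if objective not in ("maximize", "minimize"):
        raise ValueError(f"unknown objective {objective!r}")
    if mode == "different-anticodon-only" and decoding_map is None:
        raise ValueError("different-anticodon-only mode needs a decoding map")
    region.check_within(len(orf))
    sign = 1.0 if objective == "maximize" else -1.0
    swaps = []
    for k in region.codon_indices():
        source = orf.codons[k - 1]
        candidates = [c for c in synonymous_codons(source) if c in table.w]
        if mode == "different-anticodon-only":
            src_set = decoding_map.anticodons_for(source)
            candidates = [
                c for c in candidates
                if c == source or decoding_map.anticodons_for(c) != src_set
            ]
        # prefer source on ties (fewest edits), then lexicographic
        best = max(
            sorted(candidates),
            key=lambda c: (sign * table.w[c], c == source, _lex_key(c)),
        )
        if best != source:
            swaps.append(Swap(k, source, best))
    return _apply(
        orf, region, swaps, objective, variant_id or f"{orf.id}_{objective}", table
    )


def _lex_key(codon: str) -> tuple[int, ...]:
    # max() with this key prefers lexicographically SMALLEST codon
    return tuple(-ord(ch) for ch in codon)


@dataclass(frozen=True)
class BiasReport:
    """Codon-composition statistics of an ORF region against a binned pool."""

    region_len: int
    distinct_codons: int
    bin1_cognate_count: int
    bin1_cognate_fraction: float
    weak_codon_count: int
    nnu_nnc_ratios: dict[str, tuple[int, int]]
    bin1_clusters: tuple[Region, ...]


def bias_statistics(
    orf: OrfSequence,
    region: Region,
    decoding_map: DecodingMap,
    partition: BinPartition,
    bin1_rule: Literal["all-decoders", "any-decoder"] = "all-decoders",
) -> BiasReport:
    """Codon-bias statistics of a region: reliance on the lowest-abundance
    (bin-1) tRNAs, all-A/U "weak" codons, and U- vs C-ending usage within
    two-codon pyrimidine families.

    A codon is bin-1-cognate when all of its decoding anticodons sit in bin 1
    (``all-decoders``, the strict reading: the codon *must* be decoded by a
    bin-1 tRNA); ``any-decoder`` relaxes this to at least one.
    """
    region.check_within(len(orf))
    codons = [orf.codons[k - 1] for k in region.codon_indices()]

    def is_bin1(codon: str) -> bool:
        bins = [partition.assignment[ac] for ac in decoding_map.anticodons_for(codon)]
        if not bins:
            return False
        return all(b == 1 for b in bins) if bin1_rule == "all-decoders" else any(
            b == 1 for b in bins
        )

    bin1_flags = [is_bin1(c) for c in codons]
    counts = Counter(codons)
    ratios: dict[str, tuple[int, int]] = {}
    for codon in sorted(counts):
        if codon[2] not in "UC":
            continue
        family = synonymous_codons(codon)
        # only the two-codon NNU/NNC families (Asn, Asp, Cys, His, Phe, Tyr)
        if family != frozenset({codon[:2] + "U", codon[:2] + "C"}):
            continue
        nnu = counts.get(codon[:2] + "U", 0)
        nnc = counts.get(codon[:2] + "C", 0)
        ratios[translate_codon(codon)] = (nnu, nnc)

    clusters = []
    run_start = None
    for offset, flag in enumerate([*bin1_flags, False]):
        if flag and run_start is None:
            run_start = offset
        elif not flag and run_start is not None:
            if offset - run_start >= 2:
                clusters.append(
                    Region(start=region.start + run_start, end=region.start + offset - 1)
                )
            run_start = None

    return BiasReport(
        region_len=len(codons),
        distinct_codons=len(counts),
        bin1_cognate_count=sum(bin1_flags),
        bin1_cognate_fraction=sum(bin1_flags) / len(codons),
        weak_codon_count=sum(1 for c in codons if set(c) <= {"A", "U"}),
        nnu_nnc_ratios=ratios,
        bin1_clusters=tuple(clusters),
    )
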