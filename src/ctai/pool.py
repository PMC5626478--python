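"""Anticodon-level tRNA pools: read-count tables, abundance bins, decoding maps.

The measured input is a table with one row per tRNA anticodon species: the
anticodon (5'→3', so the wobble base at position 34 is the FIRST letter), the
amino acid it carries, its mapped mature read count, and the set of sense
codons it decodes. The codon column is authoritative for decodability: the
decoding map never adds codon→anticodon edges from pairing rules alone, so a
table that lists an unusual wobble decoding (e.g. ACC under a U34 anticodon)
keeps it, and one that omits a geometrically possible pairing stays without it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import PairingError, PoolValidationError
from .genetic_code import (
    RNA_BASES,
    SENSE_CODONS,
    WC_PARTNER,
    normalize_rna,
    translate_codon,
)

__all__ = [
    "AnticodonSpecies",
    "TRNAPool",
    "BinPartition",
    "PairingClass",
    "DecodingMap",
    "expand_codon_shorthand",
    "load_pool",
    "assign_bins",
    "bin_summary",
    "classify_pairing",
    "build_decoding_map",
]


@dataclass(frozen=True)
class AnticodonSpecies:
    """One tRNA anticodon species with its abundance and decoding capability."""

    anticodon: str
    amino_acid: str
    read_count: int
    decoded_codons: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "anticodon", normalize_rna(self.anticodon))
        object.__setattr__(
            self, "decoded_codons", frozenset(normalize_rna(c) for c in self.decoded_codons)
        )
        if len(self.anticodon) != 3 or set(self.anticodon) - RNA_BASES:
            raise PoolValidationError(f"invalid anticodon {self.anticodon!r}")
        if not isinstance(self.read_count, int) or isinstance(self.read_count, bool):
            raise PoolValidationError(
                f"{self.anticodon}: read count must be an integer, got {self.read_count!r}"
            )
        if self.read_count < 0:
            raise PoolValidationError(
                f"{self.anticodon}: negative read count {self.read_count}"
            )
        if not self.decoded_codons:
            raise PoolValidationError(f"{self.anticodon}: no decoded codons")
        stems = {c[:2] for c in self.decoded_codons}
        if len(stems) != 1:
            raise PoolValidationError(
                f"{self.anticodon}: decoded codons {sorted(self.decoded_codons)} "
                "differ outside position 3"
            )
        for codon in self.decoded_codons:
            aa = translate_codon(codon)
            if aa != self.amino_acid:
                raise PoolValidationError(
                    f"anticodon {self.anticodon}: codon {codon} translates to {aa}, "
                    f"not {self.amino_acid}"
                )

    @property
    def wobble_base(self) -> str:
        """Anticodon position-34 base (first letter, pairs with codon base 3)."""
        return self.anticodon[0]


@dataclass(frozen=True)
class TRNAPool:
    """An ordered collection of anticodon species from one tRNA-seq experiment."""

    species: tuple[AnticodonSpecies, ...]
    total_reads: int = field(init=False)

    def __post_init__(self) -> None:
        anticodons = [s.anticodon for s in self.species]
        seen: set[str] = set()
        for ac in anticodons:
            if ac in seen:
                raise PoolValidationError(f"duplicate anticodon {ac}")
            seen.add(ac)
        object.__setattr__(self, "total_reads", sum(s.read_count for s in self.species))

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, anticodon: str) -> AnticodonSpecies:
        anticodon = normalize_rna(anticodon)
        for s in self.species:
            if s.anticodon == anticodon:
                return s
        raise KeyError(anticodon)

    @property
    def decoded_codons(self) -> frozenset[str]:
        return frozenset().union(*(s.decoded_codons for s in self.species))

    def is_complete(self) -> bool:
        """True when the union of decoded codons is all 61 sense codons."""
        return self.decoded_codons == SENSE_CODONS

    def without(self, anticodon: str) -> "TRNAPool":
        anticodon = normalize_rna(anticodon)
        return TRNAPool(tuple(s for s in self.species if s.anticodon != anticodon))


def expand_codon_shorthand(shorthand: str) -> frozenset[str]:
    """Expand slash shorthand like ``ACA/G/C`` to {ACA, ACG, ACC}.

    The token is a full codon optionally followed by single-base third-position
    alternatives. A plain codon maps to itself.
    """
    token = normalize_rna(shorthand)
    parts = token.split("/")
    head = parts[0]
    if len(head) != 3 or set(head) - RNA_BASES:
        raise PoolValidationError(f"malformed codon token {shorthand!r}")
    codons = {head}
    for alt in parts[1:]:
        if len(alt) != 1 or alt not in RNA_BASES:
            raise PoolValidationError(
                f"malformed third-position alternative {alt!r} in {shorthand!r}"
            )
        codons.add(head[:2] + alt)
    return frozenset(codons)


def _parse_codons_cell(cell: str) -> frozenset[str]:
    codons: set[str] = set()
    for token in cell.replace(";", ",").split(","):
        token = token.strip()
        if token:
            codons |= expand_codon_shorthand(token)
    if not codons:
        raise PoolValidationError(f"empty codons cell {cell!r}")
    return frozenset(codons)


REQUIRED_COLUMNS = ("anticodon", "amino_acid", "read_count", "codons")


def load_pool(table_text: str) -> TRNAPool:
    """Parse a tab-separated tRNA read-count table into a validated pool.

    Expected header columns: ``anticodon``, ``amino_acid``, ``read_count``,
    ``codons`` (comma-separated full codons or slash shorthand). ``#`` comment
    lines are ignored; DNA-alphabet input is normalized to RNA.
    """
    lines = [ln for ln in table_text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise PoolValidationError("empty table")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise PoolValidationError(f"missing columns: {', '.join(missing)}")
    idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
    species = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        raw_count = cells[idx["read_count"]].strip().replace(",", "")
        try:
            count = int(raw_count)
        except ValueError:
            raise PoolValidationError(f"non-integer read count {raw_count!r}") from None
        if float(raw_count) != count:
            raise PoolValidationError(f"non-integer read count {raw_count!r}")
        species.append(
            AnticodonSpecies(
                anticodon=cells[idx["anticodon"]].strip(),
                amino_acid=cells[idx["amino_acid"]].strip().upper(),
                read_count=count,
                decoded_codons=_parse_codons_cell(cells[idx["codons"]]),
            )
        )
    return TRNAPool(tuple(species))


@dataclass(frozen=True)
class BinPartition:
    """Assignment of anticodon species to abundance bins, 1 = lowest counts.

    Bins are contiguous in ascending read-count rank and as equal-sized as
    possible. With a remainder r, the extra species go to the middle bins first
    (middle-outward, later bin first on ties), so 45 species in 4 bins gives
    sizes (11, 11, 12, 11).
    """

    n_bins: int
    assignment: dict[str, int]

    def members(self, bin_index: int) -> list[str]:
        return [ac for ac, b in self.assignment.items() if b == bin_index]


def _bin_sizes(n_species: int, n_bins: int) -> list[int]:
    base, remainder = divmod(n_species, n_bins)
    sizes = [base] * n_bins
    center = (n_bins + 1) / 2
    order = sorted(range(n_bins), key=lambda i: (abs((i + 1) - center), -(i + 1)))
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def _ranked(pool: TRNAPool) -> list[AnticodonSpecies]:
    # ties broken by anticodon lexicographic order for determinism
    return sorted(pool.species, key=lambda s: (s.read_count, s.anticodon))


def assign_bins(pool: TRNAPool, n_bins: int = 4) -> BinPartition:
    """Partition species into *n_bins* rank-contiguous abundance bins."""
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if not len(pool):
        raise ValueError("empty pool")
    if n_bins > len(pool):
        raise ValueError(f"n_bins={n_bins} exceeds pool size {len(pool)}")
    ranked = _ranked(pool)
    sizes = _bin_sizes(len(ranked), n_bins)
    assignment: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(sizes, start=1):
        for s in ranked[pos : pos + size]:
            assignment[s.anticodon] = b
        pos += size
    return BinPartition(n_bins=n_bins, assignment=assignment)


def bin_summary(pool: TRNAPool, partition: BinPartition) -> pd.DataFrame:
    """Per-bin species count, read sum and fraction of total reads.

    Fractions use the pool's actual total (the sum of all read counts) and sum
    to 1 to within 1e-12.
    """
    if set(partition.assignment) != {s.anticodon for s in pool.species}:
        raise ValueError("partition does not match pool species")
    rows = []
    total = pool.total_reads
    for b in range(1, partition.n_bins + 1):
        members = set(partition.members(b))
        reads = sum(s.read_count for s in pool.species if s.anticodon in members)
        rows.append(
            {
                "bin": b,
                "n_species": len(members),
                "read_sum": reads,
                "fraction": reads / total if total else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


class PairingClass(enum.Enum):
    """Codon position-3 : anticodon position-34 pairing classes.

    Named codon3:anticodon34. ``WC`` covers the four Watson:Crick pairs; the
    inosine classes (UI, CI, AI) apply when a genomically-A34 anticodon is read
    as inosine-modified.
    """

    WC = "WC"
    UG = "U:G"
    CI = "C:I"
    GU = "G:U"
    AI = "A:I"
    AG = "A:G"
    UI = "U:I"
    CU = "C:U"
    UU = "U:U"


_LITERAL_CLASSES = {
    ("U", "G"): PairingClass.UG,
    ("G", "U"): PairingClass.GU,
    ("A", "G"): PairingClass.AG,
    ("C", "U"): PairingClass.CU,
    ("U", "U"): PairingClass.UU,
}

_INOSINE_CLASSES = {"U": PairingClass.UI, "C": PairingClass.CI, "A": PairingClass.AI}


def classify_pairing(
    codon: str, species: AnticodonSpecies, inosine_rule: bool = True
) -> PairingClass:
    """Pairing class of codon base 3 against the species' wobble (34) base.

    With *inosine_rule* on (default), anticodon base A at position 34 is
    treated as inosine — the standard situation for I-arm tRNAs, and consistent
    with A34 anticodons decoding both pyrimidine-ending codons of their box.
    """
    codon = normalize_rna(codon)
    if codon not in species.decoded_codons:
        raise PairingError(f"{species.anticodon} does not decode {codon}")
    b3, b34 = codon[2], species.wobble_base
    if WC_PARTNER[b3] == b34:
        return PairingClass.WC
    if inosine_rule and b34 == "A":
        try:
            return _INOSINE_CLASSES[b3]
        except KeyError:
            raise PairingError(f"unclassifiable pair {b3}:I ({codon}:{species.anticodon})") from None
    try:
        return _LITERAL_CLASSES[(b3, b34)]
    except KeyError:
        raise PairingError(
            f"unclassifiable pair {b3}:{b34} ({codon}:{species.anticodon})"
        ) from None


@dataclass(frozen=True)
class DecodingMap:
    """Codon → [(anticodon, pairing class)] edges from one pool's codon lists."""

    edges: dict[str, tuple[tuple[str, PairingClass], ...]]
    source_pool: TRNAPool
    inosine_rule: bool = True

    @property
    def uncovered_codons(self) -> frozenset[str]:
        """Sense codons with no decoding edge in the source pool."""
        return SENSE_CODONS - frozenset(self.edges)

    def anticodons_for(self, codon: str) -> frozenset[str]:
        codon = normalize_rna(codon)
        return frozenset(ac for ac, _ in self.edges.get(codon, ()))


def build_decoding_map(pool: TRNAPool, inosine_rule: bool = True) -> DecodingMap:
    """Build the codon→anticodon edge map, annotating each edge's pairing class.

    Coverage gaps (sense codons no species decodes) are reported through
    ``DecodingMap.uncovered_codons`` rather than raised; scoring raises later.
    """
    edges: dict[str, list[tuple[str, PairingClass]]] = {}
    for s in pool.species:
        for codon in sorted(s.decoded_codons):
            cls = classify_pairing(codon, s, inosine_rule=inosine_rule)
            edges.setdefault(codon, []).append((s.anticodon, cls))
    return DecodingMap(
        edges={c: tuple(v) for c, v in edges.items()},
        source_pool=pool,
        inosine_rule=inosine_rule,
    )
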