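"""ORF-level scoring: the ctAI statistic, sliding-window profiles, low regions.

The ctAI of an ORF is the geometric mean of the relative adaptiveness w of its
codons — computed in the log domain for numerical stability:

    ctAI_g = ( prod_k w_{i_k g} )^(1/l_g)

Sliding-window profiles take the mean (arithmetic by default) of w over
windows of a fixed codon length, anchored at the window start; maximal runs of
windows below a threshold become low-optimality regions, reported in codon
coordinates.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

from .adaptiveness import AdaptivenessTable
from .errors import ScoringError
from .genetic_code import STOP_CODONS, codons_of, translate_codon

__all__ = [
    "OrfSequence",
    "WindowProfile",
    "Region",
    "read_orfs_fasta",
    "score_orf",
    "window_profile",
    "detect_low_regions",
]


@dataclass(frozen=True)
class OrfSequence:
    """An in-frame coding sequence as an ordered codon list (stop excluded).

    A trailing stop codon on input is stripped; internal stops are rejected.
    Codon indices are 1-based throughout.
    """

    id: str
    codons: tuple[str, ...]

    @classmethod
    def from_nucleotides(cls, id: str, seq: str) -> "OrfSequence":
        codons = codons_of(seq)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for k, codon in enumerate(codons, start=1):
            if codon in STOP_CODONS:
                raise ValueError(f"{id}: internal stop codon {codon} at codon {k}")
        return cls(id=id, codons=tuple(codons))

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)

    @property
    def protein(self) -> str:
        return "".join(translate_codon(c) for c in self.codons)

    def subsequence(self, region: "Region", id: str | None = None) -> "OrfSequence":
        region.check_within(len(self))
        return OrfSequence(
            id=id or f"{self.id}:{region.start}-{region.end}",
            codons=self.codons[region.start - 1 : region.end],
        )

    def with_codons(self, replacements: dict[int, str], id: str) -> "OrfSequence":
        """Copy with codons replaced at 1-based indices."""
        codons = list(self.codons)
        for k, codon in replacements.items():
            codons[k - 1] = codon
        return OrfSequence(id=id, codons=tuple(codons))


@dataclass(frozen=True)
class Region:
    """1-based inclusive codon span, optionally carrying its minimum score."""

    start: int
    end: int
    min_score: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def check_within(self, orf_len: int) -> None:
        if self.end > orf_len:
            raise ValueError(f"region {self.start}-{self.end} exceeds ORF length {orf_len}")

    def codon_indices(self) -> range:
        return range(self.start, self.end + 1)

    def jaccard(self, other: "Region") -> float:
        """Codon-level Jaccard overlap with another region."""
        a, b = set(self.codon_indices()), set(other.codon_indices())
        return len(a & b) / len(a | b)

    def to_bed_line(self, orf_id: str) -> str:
        """BED (0-based half-open, nucleotide coordinates) with score=1000*min."""
        score = int(round(1000 * self.min_score)) if self.min_score is not None else 0
        return f"{orf_id}\t{(self.start - 1) * 3}\t{self.end * 3}\t{orf_id}\t{score}"


def read_orfs_fasta(source: str | io.TextIOBase) -> list[OrfSequence]:
    """Read in-frame coding sequences from FASTA (DNA or RNA; gaps stripped)."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_orfs_fasta(fh)
    return [
        OrfSequence.from_nucleotides(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")
    ]


def _codon_weights(
    orf: OrfSequence,
    table: AdaptivenessTable,
    zero_policy: Literal["error", "skip"],
) -> list[float]:
    weights = []
    for k, codon in enumerate(orf.codons, start=1):
        w = table.w.get(codon)
        if w is None or w == 0.0:
            if zero_policy == "error":
                raise ScoringError(
                    f"{orf.id}: codon {codon} at position {k} has "
                    f"{'no' if w is None else 'zero'} adaptiveness"
                )
            continue
        weights.append(w)
    return weights


def score_orf(
    orf: OrfSequence,
    table: AdaptivenessTable,
    zero_policy: Literal["error", "skip"] = "error",
) -> float:
    """ctAI of an ORF: geometric mean of per-codon w, in the log domain.

    ``zero_policy="skip"`` drops unscorable codons (for partial pools) instead
    of raising; the geometric mean is then over the scorable codons only.
    """
    weights = _codon_weights(orf, table, zero_policy)
    if not weights:
        raise ScoringError(f"{orf.id}: no scorable codons")
    return float(math.exp(np.mean(np.log(weights))))


def score_region(
    orf: OrfSequence,
    region: Region,
    table: AdaptivenessTable,
    zero_policy: Literal["error", "skip"] = "error",
) -> float:
    """ctAI of a codon span of an ORF."""
    return score_orf(orf.subsequence(region), table, zero_policy)


@dataclass(frozen=True)
class WindowProfile:
    """Per-window mean adaptiveness along an ORF, anchored at window starts."""

    orf_id: str
    window_len: int
    scores: tuple[float, ...]
    anchor: int = 1

    def __len__(self) -> int:
        return len(self.scores)

    def anchors(self) -> range:
        """1-based codon index of each window's first codon."""
        return range(self.anchor, self.anchor + len(self.scores))

    def plot(self, ax=None, threshold: float = 0.4):
        """Line plot of the profile; stretches below *threshold* drawn in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        x = np.asarray(self.anchors())
        y = np.asarray(self.scores)
        ax.plot(x, y, color="0.3", lw=1)
        below = y < threshold
        ax.scatter(x[below], y[below], color="red", s=6, zorder=3)
        ax.axhline(threshold, color="red", lw=0.5, ls="--")
        ax.set_xlabel("codon")
        ax.set_ylabel(f"mean w ({self.window_len}-codon window)")
        ax.set_ylim(0, 1)
        ax.set_title(self.orf_id)
        return ax


def window_profile(
    orf: OrfSequence,
    table: AdaptivenessTable,
    window_len: int = 10,
    mean_kind: Literal["arithmetic", "geometric"] = "arithmetic",
) -> WindowProfile:
    """Sliding-window mean of per-codon w, stride 1, anchored at window starts."""
    if window_len < 1:
        raise ValueError(f"window_len must be >= 1, got {window_len}")
    if len(orf) < window_len:
        raise ValueError(
            f"{orf.id}: ORF length {len(orf)} shorter than window {window_len}"
        )
    w = np.array([_lookup(orf, k, table) for k in range(1, len(orf) + 1)])
    if mean_kind == "geometric":
        if (w <= 0).any():
            raise ScoringError(f"{orf.id}: zero adaptiveness codon in geometric window")
        values = np.exp(_sliding_mean(np.log(w), window_len))
    else:
        values = _sliding_mean(w, window_len)
    return WindowProfile(
        orf_id=orf.id, window_len=window_len, scores=tuple(float(v) for v in values)
    )


def _lookup(orf: OrfSequence, k: int, table: AdaptivenessTable) -> float:
    codon = orf.codons[k - 1]
    try:
        return table.w[codon]
    except KeyError:
        raise ScoringError(f"{orf.id}: codon {codon} at position {k} not in table") from None


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def detect_low_regions(
    profile: WindowProfile,
    threshold: float = 0.4,
    min_windows: int = 1,
    merge_gap: int = 0,
) -> list[Region]:
    """Maximal runs of sub-threshold windows, as codon-coordinate regions.

    Runs shorter than *min_windows* are dropped; runs separated by at most
    *merge_gap* windows are merged. Each region spans the union of its member
    windows' codons and carries the minimum window score inside its runs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not len(profile):
        raise ValueError("empty profile")
    runs = _runs_below(profile.scores, threshold)
    runs = [r for r in runs if r[1] - r[0] + 1 >= min_windows]
    merged: list[list[int]] = []
    for lo, hi in runs:
        if merged and lo - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    regions = []
    for lo, hi in merged:
        scores = profile.scores[lo : hi + 1]
        regions.append(
            Region(
                start=profile.anchor + lo,
                end=profile.anchor + hi + profile.window_len - 1,
                min_score=min(scores),
            )
        )
    return regions


def _runs_below(scores: Iterable[float], threshold: float) -> list[tuple[int, int]]:
    scores = list(scores)
    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(scores):
        if s < threshold:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(scores) - 1))
    return runs
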