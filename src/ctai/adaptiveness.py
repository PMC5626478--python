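"""Per-codon adaptiveness to a measured tRNA pool.

Absolute adaptiveness of codon i sums the read counts of every anticodon j
that decodes it, each discounted by the pairing-class penalty s_ij:

    W_i = sum_j (1 - s_ij) * tRC_ij

Relative adaptiveness normalizes within the synonymous (isoacceptor) family,
with a read-count floor on the denominator so that families whose best tRNA is
itself scarce do not score as artificially optimal:

    w_i = W_i / max(max_family W, read_cap)

The default cap of 80,000 reads is roughly the third quartile of the measured
HEK293 pool. Penalties default to the values fitted against construct
expression data (U:G = 0.6, C:I = 0.3, G:U = 0.8, A:I = 0.5, A:G = 0.9999);
the C:U and U:U classes, which occur in the measured decoding table but have
no published penalty, default to 0.6 and are explicitly configurable, and U:I
defaults to 0 (inosine reads U at cognate strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError
from .genetic_code import normalize_rna, translate_codon
from .pool import DecodingMap, PairingClass

__all__ = ["ConstraintTable", "AdaptivenessTable", "absolute_adaptiveness", "relative_adaptiveness"]

DEFAULT_S: dict[PairingClass, float] = {
    PairingClass.WC: 0.0,
    PairingClass.UG: 0.6,
    PairingClass.CI: 0.3,
    PairingClass.GU: 0.8,
    PairingClass.AI: 0.5,
    PairingClass.AG: 0.9999,
    PairingClass.UI: 0.0,
    PairingClass.CU: 0.6,
    PairingClass.UU: 0.6,
}

DEFAULT_READ_CAP = 80_000.0


@dataclass(frozen=True)
class ConstraintTable:
    """Pairing-class penalties s (in [0, 1]) and the normalization read cap.

    Set ``read_cap=None`` to disable the floor (denominator is then the family
    maximum alone, making downstream scores invariant to uniform read-count
    scaling).
    """

    s: dict[PairingClass, float] = field(default_factory=lambda: dict(DEFAULT_S))
    read_cap: float | None = DEFAULT_READ_CAP

    def __post_init__(self) -> None:
        for cls, value in self.s.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"s({cls.value}) = {value} outside [0, 1]")
            if value == 1.0:
                warnings.warn(
                    f"s({cls.value}) = 1 zeroes every {cls.value} edge", stacklevel=2
                )
        if self.read_cap is not None and self.read_cap <= 0:
            raise ConfigurationError(f"read_cap must be positive, got {self.read_cap}")

    def with_s(self, **updates: float) -> "ConstraintTable":
        """Copy with penalties replaced by class name, e.g. ``with_s(UG=0.5)``."""
        s = dict(self.s)
        for name, value in updates.items():
            s[PairingClass[name]] = value
        return replace(self, s=s)

    def penalty(self, cls: PairingClass) -> float:
        try:
            return self.s[cls]
        except KeyError:
            raise ConfigurationError(f"no penalty configured for class {cls.value}") from None


@dataclass(frozen=True)
class AdaptivenessTable:
    """Absolute (W) and family-normalized relative (w) adaptiveness per codon."""

    W: dict[str, float]
    w: dict[str, float]
    group_of: dict[str, str]
    read_cap: float | None

    def __getitem__(self, codon: str) -> float:
        return self.w[normalize_rna(codon)]

    def __contains__(self, codon: str) -> bool:
        return normalize_rna(codon) in self.w


def absolute_adaptiveness(
    decoding_map: DecodingMap, constraints: ConstraintTable
) -> dict[str, float]:
    """W per codon: penalty-discounted read-count sum over its decoding edges.

    Codons with no edge in the map are absent from the result.
    """
    counts = {s.anticodon: s.read_count for s in decoding_map.source_pool.species}
    W: dict[str, float] = {}
    for codon, edges in decoding_map.edges.items():
        W[codon] = sum((1.0 - constraints.penalty(cls)) * counts[ac] for ac, cls in edges)
    return W


def relative_adaptiveness(
    W: dict[str, float], constraints: ConstraintTable
) -> AdaptivenessTable:
    """Normalize W within synonymous families against max(family max, cap)."""
    group_of = {codon: translate_codon(codon) for codon in W}
    group_max: dict[str, float] = {}
    for codon, value in W.items():
        aa = group_of[codon]
        group_max[aa] = max(group_max.get(aa, 0.0), value)
    cap = constraints.read_cap
    w: dict[str, float] = {}
    for codon, value in W.items():
        denom = group_max[group_of[codon]]
        if cap is not None:
            denom = max(denom, cap)
        if denom <= 0:
            raise ConfigurationError(
                f"family {group_of[codon]} has no positive W and no cap"
            )
        w[codon] = value / denom
    return AdaptivenessTable(W=dict(W), w=w, group_of=group_of, read_cap=cap)


def adaptiveness_from_map(
    decoding_map: DecodingMap, constraints: ConstraintTable | None = None
) -> AdaptivenessTable:
    """Convenience: W then w from a decoding map in one call."""
    constraints = constraints or ConstraintTable()
    return relative_adaptiveness(absolute_adaptiveness(decoding_map, constraints), constraints)
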