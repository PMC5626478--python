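"""Packaged data: the measured HEK293 tRNA read-count table and the synthetic
CRD construct series (see :mod:`ctai.data.synthetic_crd`)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from ..pool import TRNAPool, load_pool
from .synthetic_crd import (  # noqa: F401
    CRD_SPAN,
    EXPECTED_CTAI_ORDER,
    WT_CODONS,
    crd_constructs,
    crd_region,
)

__all__ = [
    "hek293_pool",
    "hek293_table_text",
    "crd_constructs",
    "crd_region",
    "CRD_SPAN",
    "WT_CODONS",
    "EXPECTED_CTAI_ORDER",
]


def hek293_table_text() -> str:
    """Raw TSV text of the measured HEK293 anticodon read-count table."""
    return (
        resources.files(__package__).joinpath("hek293_trna_counts.tsv").read_text()
    )


@lru_cache(maxsize=1)
def hek293_pool() -> TRNAPool:
    """The measured HEK293 anticodon pool, validated (45 species, 61 codons)."""
    return load_pool(hek293_table_text())
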