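"""tRNA pool loading, shorthand expansion, binning and decoding maps."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctai import (
    AnticodonSpecies,
    PairingClass,
    TRNAPool,
    assign_bins,
    bin_summary,
    build_decoding_map,
    classify_pairing,
    expand_codon_shorthand,
    load_pool,
)
from ctai.errors import PairingError, PoolValidationError


@pytest.mark.parametrize(
    "shorthand, expected",
    [
        ("ACA/G/C", {"ACA", "ACG", "ACC"}),
        ("AUG", {"AUG"}),
        ("CCA/G/U", {"CCA", "CCG", "CCU"}),
        ("TGT", {"UGU"}),  # DNA input normalized
    ],
)
def test_shorthand_expansion(shorthand, expected):
    assert expand_codon_shorthand(shorthand) == frozenset(expected)


@pytest.mark.parametrize("bad", ["AC", "ACA/GG", "ACA//", "ACA/X", "AXA"])
def test_shorthand_rejects_malformed_tokens(bad):
    with pytest.raises(PoolValidationError):
        expand_codon_shorthand(bad)


def test_measured_pool_loads_and_validates(pool):
    assert len(pool) == 45
    assert pool.total_reads == sum(s.read_count for s in pool.species)
    assert pool.is_complete()
    met = pool["CAU"]
    assert met.amino_acid == "M" and met.read_count == 102919


def test_single_row_table():
    p = load_pool("anticodon\tamino_acid\tread_count\tcodons\nCAT\tM\t100\tAUG\n")
    assert len(p) == 1 and p.total_reads == 100
    assert p.species[0].decoded_codons == frozenset({"AUG"})


@pytest.mark.parametrize(
    "row, message",
    [
        ("CAT\tK\t100\tAUG", "translates"),  # AUG is Met, not Lys
        ("CAT\tM\t-5\tAUG", "negative"),
        ("CAT\tM\t1.5\tAUG", "integer"),
    ],
)
def test_load_pool_validation_errors(row, message):
    text = "anticodon\tamino_acid\tread_count\tcodons\n" + row + "\n"
    with pytest.raises(PoolValidationError, match=message):
        load_pool(text)


def test_duplicate_anticodon_rejected():
    text = (
        "anticodon\tamino_acid\tread_count\tcodons\n"
        "CAT\tM\t100\tAUG\nCAT\tM\t50\tAUG\n"
    )
    with pytest.raises(PoolValidationError, match="CAU"):
        load_pool(text)


def test_species_codons_must_share_stem():
    with pytest.raises(PoolValidationError, match="position 3"):
        AnticodonSpecies("GAA", "F", 10, frozenset({"UUU", "CUU"}))


class TestBins:
    def test_measured_pool_bin_sizes(self, pool, partition):
        sizes = [len(partition.members(b)) for b in (1, 2, 3, 4)]
        assert sizes == [11, 11, 12, 11]

    def test_measured_pool_bin_sums(self, pool, partition):
        summary = bin_summary(pool, partition)
        assert list(summary["read_sum"]) == [139896, 288474, 556065, 1611710]
        assert summary["read_sum"].sum() == pool.total_reads

    def test_measured_pool_bin_fractions(self, pool, partition):
        fractions = list(bin_summary(pool, partition)["fraction"])
        # the coarse published percentages: 5.4, 11, 21, 62
        assert [round(100 * f, 1) for f in fractions] == [5.4, 11.1, 21.4, 62.1]
        assert math.isclose(sum(fractions), 1.0, abs_tol=1e-12)

    def test_bijection_when_bins_equal_species(self):
        p = _toy_pool([("CAT", "M", 5, "AUG"), ("CCA", "W", 9, "UGG"),
                       ("GAA", "F", 2, "UUU/C"), ("TAC", "V", 7, "GUA")])
        part = assign_bins(p, 4)
        ranked = sorted(p.species, key=lambda s: s.read_count)
        assert [part.assignment[s.anticodon] for s in ranked] == [1, 2, 3, 4]

    def test_two_bins_agree_with_full_sort(self):
        rows = [("CAT", "M", 30, "AUG"), ("CCA", "W", 10, "UGG"),
                ("GAA", "F", 80, "UUU/C"), ("TAC", "V", 50, "GUA"),
                ("TAT", "I", 20, "AUA"), ("TTG", "Q", 70, "CAA"),
                ("CGT", "T", 60, "ACG"), ("CGG", "P", 40, "CCG")]
        p = _toy_pool(rows)
        part = assign_bins(p, 2)
        smallest = {s.anticodon for s in sorted(p.species, key=lambda s: s.read_count)[:4]}
        assert set(part.members(1)) == smallest

    def test_bad_n_bins(self, pool):
        with pytest.raises(ValueError):
            assign_bins(pool, 0)

    def test_equal_counts_give_half_fractions(self):
        p = _toy_pool([("CAT", "M", 10, "AUG"), ("CCA", "W", 10, "UGG")])
        fractions = list(bin_summary(p, assign_bins(p, 2))["fraction"])
        assert fractions == [0.5, 0.5]

    def test_partition_pool_mismatch_raises(self, pool):
        part = assign_bins(pool)
        with pytest.raises(ValueError, match="match"):
            bin_summary(pool.without("CAU"), part)

    @settings(deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 10**6), min_size=4, max_size=50),
           data=st.data())
    def test_bins_contiguous_and_balanced_for_random_pools(self, counts, data):
        """Bins are rank-contiguous with sizes differing by at most one, and
        fractions always sum to 1 — checked against a brute-force sort."""
        rows = [(_ANTICODONS[i][0], _ANTICODONS[i][1], c, _ANTICODONS[i][2])
                for i, c in enumerate(counts[: len(_ANTICODONS)])]
        p = _toy_pool(rows)
        n_bins = data.draw(st.integers(1, len(p)))
        part = assign_bins(p, n_bins)
        ranked = sorted(p.species, key=lambda s: (s.read_count, s.anticodon))
        labels = [part.assignment[s.anticodon] for s in ranked]
        assert labels == sorted(labels)  # contiguous in rank
        sizes = [labels.count(b) for b in range(1, n_bins + 1)]
        assert max(sizes) - min(sizes) <= 1
        if p.total_reads:
            assert math.isclose(bin_summary(p, part)["fraction"].sum(), 1.0, abs_tol=1e-12)
        assert assign_bins(p, n_bins).assignment == part.assignment  # idempotent


class TestPairing:
    def test_wobble_ug(self, pool):
        assert classify_pairing("UAU", pool["GUA"]) is PairingClass.UG

    def test_watson_crick(self, pool):
        assert classify_pairing("ACA", pool["UGU"]) is PairingClass.WC

    def test_inosine_ci(self, pool):
        assert classify_pairing("CCC", pool["AGG"]) is PairingClass.CI
        # without the inosine rule a literal C:A pair has no class
        with pytest.raises(PairingError):
            classify_pairing("CCC", pool["AGG"], inosine_rule=False)
        # U against genomic A34 is Watson:Crick whether or not A is read as I
        assert classify_pairing("CCU", pool["AGG"], inosine_rule=False) is PairingClass.WC
        assert classify_pairing("CCU", pool["AGG"]) is PairingClass.WC

    def test_undecodable_codon_raises(self, pool):
        with pytest.raises(PairingError):
            classify_pairing("AUG", pool["GUA"])


class TestDecodingMap:
    def test_acg_has_two_edges(self, pool, decoding_map):
        edges = dict(decoding_map.edges["ACG"])
        assert edges == {"CGU": PairingClass.WC, "UGU": PairingClass.GU}

    def test_aug_single_wc_edge(self, decoding_map):
        assert decoding_map.edges["AUG"] == (("CAU", PairingClass.WC),)

    def test_complete_pool_covers_61_codons(self, decoding_map):
        assert not decoding_map.uncovered_codons
        assert len(decoding_map.edges) == 61

    def test_missing_trp_species_reported_uncovered(self, pool):
        gapped = build_decoding_map(pool.without("CCA"))
        assert gapped.uncovered_codons == frozenset({"UGG"})

    def test_edges_retranslate_to_species_amino_acid(self, pool, decoding_map):
        from ctai.genetic_code import translate_codon

        for codon, edges in decoding_map.edges.items():
            for anticodon, _ in edges:
                assert translate_codon(codon) == pool[anticodon].amino_acid


_ANTICODONS = [
    ("CAT", "M", "AUG"), ("CCA", "W", "UGG"), ("GAA", "F", "UUU/C"),
    ("TAC", "V", "GUA"), ("TAT", "I", "AUA"), ("TTG", "Q", "CAA"),
    ("CGT", "T", "ACG"), ("CGG", "P", "CCG"), ("GTG", "H", "CAU/C"),
    ("GTC", "D", "GAU/C"), ("GCA", "C", "UGU/C"), ("TTC", "E", "GAA"),
    ("TTT", "K", "AAA"), ("GTT", "N", "AAU/C"), ("GTA", "Y", "UAU/C"),
    ("TGC", "A", "GCA"), ("TCC", "G", "GGA"), ("TCT", "R", "AGA"),
    ("TGA", "S", "UCA"), ("TAA", "L", "UUA"),
]


def _toy_pool(rows):
    return TRNAPool(
        tuple(
            AnticodonSpecies(ac, aa, count, expand_codon_shorthand(codons))
            for ac, aa, count, codons in rows
        )
    )
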