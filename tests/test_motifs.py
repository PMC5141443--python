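"""Motif model: IUPAC expansion, reverse complements, double-stranded matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aidsig.motifs import (
    DegenerateMotif,
    MotifPair,
    catalog_from_config,
    default_catalog,
    matches_at,
    motif_position_mask,
    reverse_complement_pattern,
    scan_positions_bruteforce,
)


class TestDegenerateMotif:
    def test_invalid_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            DegenerateMotif("bad", "WXC", 2)

    def test_mutable_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            DegenerateMotif("bad", "WRC", 3)

    def test_mutable_base_must_be_at_most_twofold(self):
        with pytest.raises(ValueError, match="two-fold"):
            DegenerateMotif("bad", "WNC", 1)
        # two-fold codes are fine (the W of TW marks an A/T-prone class)
        DegenerateMotif("ok", "TW", 1)

    @pytest.mark.parametrize(
        "pattern,index,expected",
        [
            ("WRC", 2, {"AAC", "AGC", "TAC", "TGC"}),
            ("CG", 0, {"CG"}),
        ],
    )
    def test_expand_examples(self, pattern, index, expected):
        assert DegenerateMotif(pattern, pattern, index).expand() == frozenset(expected)

    def test_expand_size_is_degeneracy_product(self):
        assert len(DegenerateMotif("SNCG", "SNCG", 2).expand()) == 2 * 4

    @pytest.mark.parametrize(
        "pattern,index,rc_pattern,rc_index",
        [
            ("WRC", 2, "GYW", 0),
            ("WRCG", 2, "CGYW", 1),
            ("CG", 0, "CG", 1),
            ("TCW", 1, "WGA", 1),
        ],
    )
    def test_reverse_complement_examples(self, pattern, index, rc_pattern, rc_index):
        rc = DegenerateMotif(pattern, pattern, index).reverse_complement()
        assert rc.pattern == rc_pattern
        assert rc.mutable_index == rc_index

    def test_reverse_complement_is_involution(self, catalog):
        for pair in catalog.values():
            m = pair.forward
            assert m.reverse_complement().reverse_complement() == m


class TestMotifPair:
    def test_mismatched_reverse_rejected(self):
        fwd = DegenerateMotif("WRC", "WRC", 2)
        with pytest.raises(ValueError, match="reverse complement"):
            MotifPair(forward=fwd, reverse=fwd)

    def test_palindromic_pair(self, catalog):
        assert catalog["CG"].is_palindromic
        assert not catalog["WRC"].is_palindromic

    def test_cg_pair_marks_both_bases(self, catalog):
        # strand symmetry makes both bases of a CpG mutation-prone
        assert matches_at("ACGT", 1, catalog["CG"])
        assert matches_at("ACGT", 2, catalog["CG"])
        assert not matches_at("ACGT", 0, catalog["CG"])


class TestMatching:
    def test_forward_occurrence(self, catalog):
        assert matches_at("TACG", 2, catalog["WRC"])

    def test_reverse_occurrence(self, catalog):
        # CGTA reverse-complements to TACG: the G at index 1 is the
        # mutation-prone base of the minus-strand WRC
        assert matches_at("CGTA", 1, catalog["WRC"])

    def test_masked_base_never_matches(self, catalog):
        assert not matches_at("TANG", 2, catalog["WRC"])
        for i in range(4):
            assert not matches_at("NNNN", i, catalog["WRC"])

    def test_out_of_range_position_raises(self, catalog):
        with pytest.raises(IndexError):
            matches_at("TACG", 4, catalog["WRC"])

    def test_mask_agrees_with_matches_at(self, catalog):
        seq = "TTGACGTTACGATNNCGTAA"
        for pair in catalog.values():
            mask = motif_position_mask(seq, pair)
            assert [matches_at(seq, i, pair) for i in range(len(seq))] == list(mask)

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=60),
        motif_i=st.integers(min_value=0, max_value=7),
    )
    def test_matching_matches_bruteforce_expansion_scan(self, seq, motif_i):
        pair = list(default_catalog().values())[motif_i]
        fast = motif_position_mask(seq, pair)
        slow = scan_positions_bruteforce(seq, pair)
        assert np.array_equal(fast, slow)


class TestCatalog:
    def test_catalog_patterns(self, catalog):
        assert set(catalog) == {"CG", "TCW", "WRC", "WRCH", "WRCG", "WA", "YCG", "SNCG"}
        assert catalog["WRCG"].reverse.pattern == "CGYW"

    def test_wrcg_and_controls_partition_nncg(self, catalog):
        """Every NNCG 4-mer matches WRCG at the C xor one of YCG/SNCG."""
        bases = "ACGT"
        n_wrcg = 0
        for b1 in bases:
            for b2 in bases:
                word = b1 + b2 + "CG"
                target = matches_at(word, 2, catalog["WRCG"])
                control = matches_at(word, 2, catalog["YCG"]) or matches_at(
                    word, 2, catalog["SNCG"]
                )
                assert target != control, word
                n_wrcg += target
        assert n_wrcg == 4  # {A,T} x {A,G} prefixes

    def test_catalog_from_config_roundtrip(self):
        cat = catalog_from_config([("WRC", "WRC", 2), ("CG", "CG", 0)])
        assert cat["WRC"].reverse.pattern == "GYW"
        assert reverse_complement_pattern("WRCH") == "DGYW"
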