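"""CpG occurrence classification and the WRCG-vs-control contrast."""

import itertools

import pytest

from aidsig.contrast import (
    classify_prefix,
    contrast_on_neighborhoods,
    contrast_test,
    enumerate_cpg_occurrences_in_regions,
    enumerate_cpg_occurrences_in_windows,
)
from aidsig.io import MutationRecord

from conftest import make_record


def _windows(seqs, center=4, spacing=300):
    return [make_record(s, center, pos=100 + spacing * i) for i, s in enumerate(seqs)]


class TestClassification:
    def test_wrcg_prefix(self):
        # TACGA: the CG at offset 2 is preceded by T (W) and A (R)
        occs = enumerate_cpg_occurrences_in_windows(_windows(["TTTACGATT"], center=4))
        plus = [o for o in occs if o.orientation == "+"]
        assert len(plus) == 1 and plus[0].is_target

    def test_ycg_prefix_is_control(self):
        # TCCGA: the base before the CG is C, a Y — control class
        occs = enumerate_cpg_occurrences_in_windows(_windows(["TTTCCGATT"], center=4))
        plus = [o for o in occs if o.orientation == "+"]
        assert len(plus) == 1 and not plus[0].is_target

    def test_minus_strand_occurrence(self):
        # CGTA read on the minus strand is TACG: target, prone base = the G
        occs = enumerate_cpg_occurrences_in_windows(_windows(["TTTCGTATT"], center=4))
        minus = [o for o in occs if o.orientation == "-"]
        assert len(minus) == 1 and minus[0].is_target
        assert minus[0].mutable_pos == minus[0].pos + 1

    def test_prefix_partition_counts(self):
        """All 16 NNCG prefixes: 4 target ({A,T}x{A,G}) and 12 control."""
        labels = [
            classify_prefix(b1, b2) for b1, b2 in itertools.product("ACGT", repeat=2)
        ]
        assert sum(labels) == 4 and len(labels) == 16
        assert all(l is not None for l in labels)

    def test_edge_cg_without_prefix_excluded(self):
        # CG at the very window start has no upstream bases on the plus strand
        occs = enumerate_cpg_occurrences_in_windows(_windows(["CGTTTTTTT"], center=4))
        assert [o.orientation for o in occs] == ["-"]


class TestContrastTest:
    def _occurrences(self, n_target, n_control):
        seqs = ["TTTACGATT"] * n_target  # + strand target, C at the center
        seqs += ["TTTCCGATT"] * n_control  # + strand control (YCG)
        return _windows(seqs)

    def test_symmetric_table_p_one(self):
        windows = self._occurrences(6, 6)
        # hit one target C and one control C
        hits = [MutationRecord(w.chrom, w.pos, "C", "T") for w in (windows[0], windows[6])]
        occs = [
            o
            for o in enumerate_cpg_occurrences_in_windows(windows)
            if o.orientation == "+"
        ]
        res = contrast_test(occs, hits)
        assert res.fraction_target == res.fraction_control
        assert res.fisher_p == pytest.approx(1.0)

    def test_extreme_table_exact_p(self):
        """5/5 targets mutated vs 0/5 controls: two-sided p = 1/126."""
        windows = self._occurrences(5, 5)
        hits = [MutationRecord(w.chrom, w.pos, "C", "T") for w in windows[:5]]
        occs = enumerate_cpg_occurrences_in_windows(windows)
        # restrict to plus-strand occurrences so the table is exactly 5 vs 5
        occs = [o for o in occs if o.orientation == "+"]
        res = contrast_test(occs, hits)
        assert (res.mutated_target, res.total_target) == (5, 5)
        assert (res.mutated_control, res.total_control) == (0, 5)
        assert res.fisher_p == pytest.approx(1 / 126, rel=1e-9)

    def test_duplicated_windows_do_not_change_counts(self, enriched_dataset):
        _, muts = enriched_dataset
        muts = muts[:300]
        base = contrast_on_neighborhoods(muts)
        doubled = contrast_on_neighborhoods(list(muts) + list(muts))
        assert (base.total_target, base.total_control) == (
            doubled.total_target,
            doubled.total_control,
        )
        assert (base.mutated_target, base.mutated_control) == (
            doubled.mutated_target,
            doubled.mutated_control,
        )

    def test_partition_conservation(self, enriched_dataset):
        """Target + control occurrence totals must cover every classifiable CG."""
        reference, muts = enriched_dataset
        muts = muts[:200]
        occs = enumerate_cpg_occurrences_in_windows(muts)
        res = contrast_test(occs, muts)
        assert res.total_target + res.total_control == len(occs)
        assert res.computable


class TestRegionMode:
    def test_region_scan_matches_window_scan_on_covering_region(self):
        seq = "TTAACGTTTCGTACGATTTTACGTT"
        muts = [make_record(seq, 12, pos=13)]  # window covers the whole contig
        from_windows = enumerate_cpg_occurrences_in_windows(muts)
        from_regions = enumerate_cpg_occurrences_in_regions(
            {"chr1": seq}, [("chr1", 0, len(seq))]
        )
        assert from_windows == from_regions

    def test_planted_enrichment_detected(self, enriched_dataset):
        _, muts = enriched_dataset
        res = contrast_on_neighborhoods(muts)
        assert res.fraction_target > res.fraction_control
        assert res.fisher_p < 1e-6
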