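"""The Fm/Fn excess statistic, its tests, masking, spectrum, Bonferroni."""

import numpy as np
import pytest

from aidsig.enrichment import (
    bonferroni,
    bonferroni_flags,
    compute_enrichment,
    excess_from_fractions,
    fisher_pvalue,
    fisher_pvalue_hypergeom,
    mask_cpg_sequence,
    spectrum_summary,
)
from aidsig.io import MutationRecord
from aidsig.motifs import reverse_complement_sequence

from conftest import make_record


class TestComputeEnrichment:
    def test_toy_hand_count(self, toy_wrc_dataset, catalog):
        r = compute_enrichment(toy_wrc_dataset, catalog["WRC"], mc_reps=0)
        assert (r.n_mutations, r.k_in_motif) == (4, 2)
        assert (r.motif_positions, r.total_positions) == (2, 12)
        assert r.fm == pytest.approx(0.5)
        assert r.fn == pytest.approx(2 / 12)
        assert r.excess == pytest.approx(3.0)
        assert r.fisher_p == pytest.approx(
            fisher_pvalue_hypergeom(2, 4, 2, 12), rel=1e-9
        )

    def test_no_motif_anywhere_gives_zero_fm(self, catalog):
        muts = [make_record("TTTTATTT", 4, pos=100 + 200 * i) for i in range(3)]
        r = compute_enrichment(muts, catalog["WRC"], mc_reps=0)
        assert r.k_in_motif == 0 and r.motif_positions == 0
        assert not r.computable and r.excess is None

    def test_mask_cpg_drops_cpg_centered_mutations(self, catalog):
        muts = [make_record("AATACGTT", 4, pos=100 + 200 * i) for i in range(3)]
        r = compute_enrichment(muts, catalog["WRC"], mask_cpg=True, mc_reps=0)
        assert r.n_mutations == 0 and r.n_dropped_masked == 3

    def test_published_fraction_arithmetic(self):
        assert round(excess_from_fractions(0.265, 0.222), 2) == 1.19

    def test_empty_mutation_set_is_error(self, catalog):
        with pytest.raises(ValueError, match="empty"):
            compute_enrichment([], catalog["WRC"])

    def test_excess_invariant_under_dataset_reverse_complement(
        self, enriched_dataset, catalog
    ):
        reference, muts = enriched_dataset
        genome_length = len(reference)
        muts = muts[:300]
        # strand flip of the whole dataset: sequences reverse-complemented and
        # genomic coordinates mirrored so window bookkeeping stays consistent
        flipped = [
            MutationRecord(
                chrom=m.chrom,
                pos=genome_length + 1 - m.pos,
                ref=reverse_complement_sequence(m.ref),
                alt=reverse_complement_sequence(m.alt),
                sample_id=m.sample_id,
                neighborhood=reverse_complement_sequence(m.neighborhood),
                center_index=len(m.neighborhood) - 1 - m.center_index,
            )
            for m in muts
        ]
        a = compute_enrichment(muts, catalog["WRCG"], mc_reps=0)
        b = compute_enrichment(flipped, catalog["WRCG"], mc_reps=0)
        assert (a.k_in_motif, a.motif_positions, a.total_positions) == (
            b.k_in_motif,
            b.motif_positions,
            b.total_positions,
        )


class TestCpGMasking:
    def test_masked_sequences_contain_no_cpg(self, enriched_dataset):
        _, muts = enriched_dataset
        for m in muts[:200]:
            assert "CG" not in mask_cpg_sequence(m.neighborhood)

    def test_mask_equals_physical_removal(self, enriched_dataset, catalog):
        """Masking CpGs must equal analysing data with CpG bases hard-removed."""
        _, muts = enriched_dataset
        muts = muts[:300]
        masked = compute_enrichment(muts, catalog["WRC"], mask_cpg=True, mc_reps=0)

        def strip_cpg(seq):  # independent removal: mark CpG bases as N
            chars = list(seq)
            for i in range(len(seq) - 1):
                if seq[i] == "C" and seq[i + 1] == "G":
                    chars[i] = chars[i + 1] = "N"
            return "".join(chars)

        physically = []
        for m in muts:
            stripped = strip_cpg(m.neighborhood)
            if stripped[m.center_index] == "N":
                continue  # CpG-context mutation removed from the dataset
            physically.append(
                MutationRecord(
                    chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                    sample_id=m.sample_id, neighborhood=stripped,
                    center_index=m.center_index,
                )
            )
        removed = compute_enrichment(physically, catalog["WRC"], mc_reps=0)
        assert masked.k_in_motif == removed.k_in_motif
        assert masked.motif_positions == removed.motif_positions
        assert masked.total_positions == removed.total_positions


class TestFisher:
    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            t = int(rng.integers(20, 400))
            k = int(rng.integers(0, n + 1))
            m = int(rng.integers(0, t + 1))
            assert fisher_pvalue(k, n, m, t) == pytest.approx(
                fisher_pvalue_hypergeom(k, n, m, t), rel=1e-7
            )


class TestMonteCarlo:
    def test_minimum_attainable_p(self, catalog):
        # every center is a motif hit; the other cytosines of each window are
        # reassignment candidates but none is a motif position (the only
        # other motif position is a G), so a replicate ties the observed
        # count only with probability 5^-8
        muts = [make_record("TTTACCCCCGTT", 4, pos=100 + 300 * i) for i in range(8)]
        r = compute_enrichment(muts, catalog["WRC"], mc_reps=999, rng_seed=5)
        assert r.k_in_motif == 8
        assert r.mc_p == pytest.approx(1 / 1000)

    def test_reps_zero_disables_mc(self, toy_wrc_dataset, catalog):
        r = compute_enrichment(toy_wrc_dataset, catalog["WRC"], mc_reps=0, rng_seed=1)
        assert r.mc_p is None

    def test_seed_reproducibility(self, enriched_dataset, catalog):
        _, muts = enriched_dataset
        a = compute_enrichment(muts[:200], catalog["WRC"], mc_reps=200, rng_seed=3)
        b = compute_enrichment(muts[:200], catalog["WRC"], mc_reps=200, rng_seed=3)
        assert a.mc_p == b.mc_p


class TestSpectrum:
    def test_transitions_at_gc(self):
        muts = [
            MutationRecord("c", 1, "C", "T"),
            MutationRecord("c", 2, "G", "A"),
        ]
        s = spectrum_summary(muts)
        assert s.transitions == 2 and s.transversions == 0
        assert s.at_gc == 2 and s.at_at == 0
        assert s.normalized_counts == {"C>T": 2}

    def test_transversion_at_at(self):
        s = spectrum_summary([MutationRecord("c", 1, "A", "T")])
        assert s.transversions == 1 and s.at_at == 1

    def test_gc_at_ratio(self):
        muts = [MutationRecord("c", i + 1, "C", "A") for i in range(6)]
        muts += [MutationRecord("c", i + 10, "A", "C") for i in range(4)]
        assert spectrum_summary(muts).gc_at_ratio == pytest.approx(1.5)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 1, True), (0.01, 10, False), (0.005, 16, False), (0.003, 16, True)],
    )
    def test_threshold(self, p, m, expected):
        flags = bonferroni_flags([p] + [1.0] * (m - 1), alpha=0.05)
        assert flags[0] is expected

    def test_none_pvalues_count_toward_m(self, toy_wrc_dataset, catalog):
        r1 = compute_enrichment(toy_wrc_dataset, catalog["WRC"], mc_reps=0)
        flagged = bonferroni([r1], alpha=1.0)
        assert flagged[0].bonferroni_significant is True
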