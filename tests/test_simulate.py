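"""Synthetic generator: sequence composition, planted rates, methylation."""

import numpy as np
import pytest
from scipy import stats

from aidsig.motifs import default_catalog, motif_position_mask
from aidsig.simulate import (
    SyntheticTruth,
    expected_cpg_count,
    generate_methylation,
    generate_mutations,
    generate_reference,
    position_weights,
    sample_ratios,
    transition_matrix,
)


class TestTruth:
    def test_serialization_roundtrip(self, tmp_path):
        truth = SyntheticTruth(genome_length=1000, theta={"WRCG": 3.0}, rng_seed=4)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert SyntheticTruth.from_json(p) == truth

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(gc_content=1.5)
        with pytest.raises(ValueError):
            SyntheticTruth(theta={"WRC": 0.0})


class TestReference:
    def test_cpg_count_matches_chain_expectation(self):
        truth = SyntheticTruth(genome_length=20_000, gc_content=0.5, cpg_enrichment=1.0)
        seq = generate_reference(truth, np.random.default_rng(1))
        expected = expected_cpg_count(truth)
        sd = np.sqrt(expected)  # CpG occurrences are nearly independent here
        assert abs(seq.count("CG") - expected) < 4 * sd

    def test_cpg_enrichment_scales_dinucleotide_frequency(self):
        lo = SyntheticTruth(genome_length=20_000, cpg_enrichment=0.25)
        hi = SyntheticTruth(genome_length=20_000, cpg_enrichment=1.0)
        assert expected_cpg_count(lo) < 0.35 * expected_cpg_count(hi)

    def test_zero_enrichment_means_no_cpg(self):
        truth = SyntheticTruth(genome_length=5_000, cpg_enrichment=0.0)
        seq = generate_reference(truth, np.random.default_rng(2))
        assert "CG" not in seq

    def test_deterministic_under_seed(self):
        truth = SyntheticTruth(genome_length=3_000, rng_seed=9)
        assert generate_reference(truth) == generate_reference(truth)

    def test_transition_matrix_rows_stochastic(self):
        T = transition_matrix(SyntheticTruth(gc_content=0.35, cpg_enrichment=0.5))
        assert np.allclose(T.sum(axis=1), 1.0)


class TestMutations:
    def test_weights_multiply_over_overlapping_motifs(self, catalog):
        # the C at index 4 is WRCG- and CG-prone; the G at 5 is CG-prone only
        # (no CGYW occurrence: the base after the G is not a Y)
        seq = "TTTACGATT"
        w = position_weights(seq, {"WRCG": 3.0, "CG": 2.0}, catalog)
        assert w[4] == pytest.approx(6.0)
        assert w[5] == pytest.approx(2.0)
        assert w[0] == pytest.approx(1.0)

    def test_uniform_under_null_theta(self):
        truth = SyntheticTruth(genome_length=20_000, n_mutations=2_000, theta={})
        rng = np.random.default_rng(3)
        ref = generate_reference(truth, rng)
        muts = generate_mutations(ref, truth, rng)
        counts, _ = np.histogram([m.pos for m in muts], bins=20, range=(1, 20_001))
        assert stats.chisquare(counts).pvalue > 0.001

    def test_extreme_theta_confines_mutations_to_motif(self, catalog):
        truth = SyntheticTruth(
            genome_length=20_000, n_mutations=100, theta={"WRC": 1e6}
        )
        rng = np.random.default_rng(4)
        ref = generate_reference(truth, rng)
        muts = generate_mutations(ref, truth, rng)
        mask = motif_position_mask(ref, catalog["WRC"])
        assert all(mask[m.pos - 1] for m in muts)

    def test_positions_unique_and_ref_consistent(self):
        truth = SyntheticTruth(genome_length=5_000, n_mutations=500)
        rng = np.random.default_rng(5)
        ref = generate_reference(truth, rng)
        muts = generate_mutations(ref, truth, rng)
        assert len({m.pos for m in muts}) == len(muts)
        assert all(ref[m.pos - 1] == m.ref for m in muts)
        assert all(m.ref != m.alt for m in muts)

    def test_too_many_mutations_is_error(self):
        truth = SyntheticTruth(genome_length=100, n_mutations=101)
        rng = np.random.default_rng(0)
        ref = generate_reference(truth, rng)
        with pytest.raises(ValueError, match="cannot place"):
            generate_mutations(ref, truth, rng)

    def test_transition_fraction_follows_parameter(self):
        truth = SyntheticTruth(
            genome_length=30_000, n_mutations=3_000, transition_prob=0.5
        )
        rng = np.random.default_rng(6)
        ref = generate_reference(truth, rng)
        muts = generate_mutations(ref, truth, rng)
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        frac = np.mean([m.alt == ts[m.ref] for m in muts])
        assert frac == pytest.approx(0.5, abs=0.03)


class TestMethylation:
    def test_depth_floor_and_count_bounds(self):
        truth = SyntheticTruth(genome_length=10_000, n_mutations=100, depth_mean=3.0)
        rng = np.random.default_rng(7)
        ref = generate_reference(truth, rng)
        muts = generate_mutations(ref, truth, rng)
        sites = generate_methylation(ref, muts, truth, rng)
        assert sites, "generator produced no CpG sites"
        assert all(s.total_reads >= 1 for s in sites)
        assert all(0 <= s.methylated_reads <= s.total_reads for s in sites)

    def test_null_delta_groups_have_equal_means(self):
        truth = SyntheticTruth()
        rng = np.random.default_rng(8)
        a = sample_ratios(4000, truth, rng, delta=0.0)
        b = sample_ratios(4000, truth, rng, delta=0.0)
        assert abs(a.mean() - b.mean()) < 2.0

    def test_planted_delta_depresses_mean(self):
        truth = SyntheticTruth()
        rng = np.random.default_rng(9)
        base = sample_ratios(6000, truth, rng, delta=0.0)
        low = sample_ratios(6000, truth, rng, delta=5.0)
        shift = base.mean() - low.mean()
        assert shift == pytest.approx(5.0, abs=1.5)
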