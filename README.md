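# aidsig

Sequence-context analysis of somatic mutations in cancer genomes: does the
mutational process prefer the degenerate target motifs of cytosine
deaminases — in particular the *hybrid* motif **WRCG/CGYW**, where the AID
deaminase motif WRC/GYW overlaps a CpG dinucleotide — beyond what local DNA
composition explains?

The package is aimed at analysts of somatic variant calls (exomes or whole
genomes) who want motif-level mutational-signature statistics with exact and
permutation significance tests, plus the companion analyses: a CpG-control
contrast, a subsampling power procedure for small cohorts, and the
association between motif context and CpG methylation ratios.

## The statistic

For each single-base substitution the 121 nt window centred on it (60 bp of
flank either side, the *DNA neighborhood*) is extracted from the reference.
For a motif pair (an IUPAC pattern with a designated mutation-prone base,
always counted on both strands):

- **Fm** — fraction of mutations whose mutated base sits at the motif's
  mutable position: `k_in_motif / n_mutations`;
- **Fn** — frequency of motif positions among un-mutated neighborhood
  positions: `motif_positions / total_positions`;
- **excess = Fm / Fn** — values above 1 mean the mutational process prefers
  the motif beyond local composition.

Significance: a two-sided Fisher exact test on
`[mutations in/out of motif] x [neighborhood positions in/out of motif]`,
and a one-sided Monte Carlo test that reassigns every mutation uniformly to
a position with the same reference base inside its own window and recounts
(add-one estimator, so 1,000 replicates floor at p = 1/1001).  Masking every
CpG (`mask_cpg`) separates CpG-driven enrichment from CpG-independent
context preference.  The hybrid contrast compares the fraction of mutated
WRCG/CGYW occurrences against the CpG contexts lacking WRC (YCG/CGR and
SNCG/CGNS, which tile all remaining NNCG contexts); the power procedure
subsamples an enrichment-positive dataset down to a small cohort's size and
reports how often the subsampled effect `Fm − Fn` exceeds the small
cohort's; the methylation module relates ratios (100 × methylated/total
reads, depth > 9) at mutated hybrid-motif CpGs vs control CpGs through a
size-matched sampling test `P(M1 ≥ M2_sampled)`.

## Worked example

The numbered scripts under `analysis/` replay the full study design on a
synthetic cohort with known truth (planted rate multipliers 3× at the
WRCG mutable C and 2× at CpG positions; a 5-point methylation depression at
mutated WRCG sites).  Running

```bash
python analysis/01_simulate_cohort.py
python analysis/02_motif_enrichment.py
```

prints (abridged):

```
motif                         excess   fisher_p    mc_p  signif
CG/CG                           2.74  7.18e-235   0.001  *
WRC/GYW                         1.68   1.82e-70   0.001  *
WRCG/CGYW                       5.20  4.28e-269   0.001  *
WRC/GYW (CpG masked)            0.98   7.36e-01   0.720
```

The hybrid motif dominates (its mutable C carries both planted multipliers,
3 × 2, hence the excess near 5), the pure AID motif shows the diluted
intermediate excess, and masking CpGs removes the WRC signal entirely —
the planted process acts only where WRC overlaps a CpG.  Script 03 shows
mutated-fraction 0.105 for WRCG occurrences vs 0.038 for CpG controls
(Fisher p ≈ 3e-80), script 04 reports that 99.9% of size-50 subsamples of an
enriched pool out-effect a flat reference (a small cohort's null result
would be meaningful), and script 05 recovers the planted methylation
depression (mean ratio 70.3 vs 76.1, sampling-test p < 1e-4) while the
mutation-agnostic comparison shows none.

The same machinery is exposed as a CLI
(`aidsig simulate | enrich | contrast | power | methylation | all`) for
running on real mutation TSV/VCF + FASTA inputs.

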