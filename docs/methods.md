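# Methods

## The excess statistic and its counting rules

Every analysis rests on position-level motif occupancy of double-stranded
DNA.  A motif is an IUPAC pattern with one designated mutation-prone base
(constrained to a concrete base or a two-fold code, so a mutation is
attributable to a prone base class); a genomic position *is a motif
position* when it aligns with that base in an occurrence of the pattern on
either strand, with a position matching both orientations counted once.
The CpG dinucleotide needs no special case: pairing `CG` (mutable index 0)
with its reverse complement `CG` (mutable index 1) marks both bases.

For a dataset of single-base substitutions, each carrying the sequence
window centred on it (`flank` = 60, giving 121 nt with 120 un-mutated local
positions), the excess of mutations in a motif is `Fm / Fn` with

- `Fm = k / n`: fraction of mutations whose mutated base is a motif
  position of its own window;
- `Fn = m / t`: motif positions among *valid* neighborhood positions,
  pooled over windows.

Valid positions exclude (i) every mutated position of the dataset that
falls inside a window, (ii) `N` bases, and (iii) window-boundary positions
whose motif status the window cannot determine (an occurrence through them
would extend past the edge).  Rule (iii) is a boundary correction: counting
undeterminable positions as non-motif deflates `Fn` and, worse, seeds the
Monte Carlo candidate pool with positions that can never count as motif
hits, biasing the test anti-conservative.  Windows truncated at contig ends
follow the same rules.

With `mask_cpg`, both bases of every CpG in each window become `N` before
any counting and mutations whose own center is masked are dropped; this
reproduces, by construction, the analysis of a dataset from which all
CpG-context positions were physically removed, and isolates CpG-independent
context preference.

## Significance tests

**Fisher.** Two-sided exact test on
`[[k, n−k], [m, t−m]]` via `scipy.stats.fisher_exact`; an independent
hypergeometric enumeration of the same two-sided tail
(`fisher_pvalue_hypergeom`) cross-checks it in the tests.

**Monte Carlo.** One replicate reassigns every mutation independently and
uniformly among its *candidates*: valid same-reference-base positions of
its own window plus the observed center itself.  Including the observed
position keeps the identity arrangement in the randomization support — a
permutation-type test without it is anti-conservative.  Because `k_i` of a
window's `m_i` candidates are motif positions, a mutation's recount
contribution is exactly a Bernoulli(`k_i/m_i`) draw, which is how the
replicates are sampled (vectorised; identical in distribution to drawing a
candidate position).  The reported p-value is the add-one estimator
`(1 + #{k* ≥ k}) / (reps + 1)`, one-sided toward enrichment, with floor
`1/(reps+1)`; a mutation with no candidate keeps its position and is
logged.  An alternative candidate rule ignoring base identity is available
(`mc_mode="any_base"`) but is not the default: conditioning on the
reference base preserves per-window base composition, as the `Fm/Fn`
statistic intends.

**Calibration and discreteness.** Exact p-values of discrete statistics
are sub-uniform by construction: the two-sided Fisher p has an atom at 1
equal to the modal table's probability (≈ `1/sqrt(2π n d(1−d))` ≈ 0.065 at
n = 200 mutations and motif density d = 0.25), and the `≥`-with-add-one
Monte Carlo estimator is conservative by about half the modal count
probability.  Uniformity diagnostics therefore use the standard
exactly-uniform constructions — the randomized (tie-smoothed)
hypergeometric PIT for Fisher and the randomized permutation p-value
`(#{k* > k} + U·(1 + #{k* = k}))/(reps+1)` for the Monte Carlo test.  These
are diagnostics only; inference always uses the conservative estimators.
On 500 independent null datasets (n = 200 each, fresh reference per
dataset) both randomized p-values pass a Kolmogorov–Smirnov uniformity
check and the raw p-values put the type-I error at α = 0.05 inside its
binomial 95% band; aggregated over 3,000 datasets the randomized versions
sit within D ≈ 0.013 of uniform.  The calibration uses the WA/TW motif,
the densest of the catalog, which keeps discreteness well below the KS
resolution; type-I behaviour is motif-agnostic.

**Multiple testing.** Bonferroni across whatever family a driver assembles
(motifs, cohorts or per-sample runs): significant iff `p ≤ α/m`;
non-computable results count toward `m` but are never significant.

## Hybrid contrast

Every CpG whose cytosine has two defined 5′ bases is classified, per
orientation, as WRCG (prefix `W·R`) or control (all other defined
prefixes — exactly the YCG ∪ SNCG tiling; the partition is enforced by an
exhaustive test).  Occurrences are keyed by (contig, C position,
orientation) and deduplicated across overlapping windows; window-edge CGs
lacking the prefix are excluded from both classes.  An occurrence is
*mutated* if any dataset mutation hits its mutation-prone base (the C for
plus-strand, the G for minus-strand occurrences).  The contrast is a
two-sided Fisher test on mutated/unmutated × target/control.  Scope
defaults to the union of mutation neighborhoods; an explicit-region mode
(BED-style intervals over a FASTA) exists for genome-scale scans.

## Power procedure

`exceed_fraction` is the share of `reps` (default 1,000) without-replacement
subsamples of the positive dataset, size-matched to the reference set,
whose effect `Fm − Fn` strictly exceeds the reference's (ties do not
exceed; each subsample's `Fn` uses its own windows).  A single reference
draw's exceedance is itself approximately uniform — it is one empirical
tail probability — so the exchangeability statement "null exceedance ≈ ½"
is checked on the mean over independent reference draws, which converges to
the Mann–Whitney exceedance probability (verified against exhaustive subset
enumeration on small inputs).

## Methylation association

Sites are per-CpG records (1-based C position, methylated/total reads,
ratio = 100·methylated/total).  The depth filter keeps `total > 9`.
Context classification reuses the contrast rules (WRCG if either
orientation matches, control if classifiable otherwise, excluded if no
orientation has defined flanks); a site is *mutated* when a mutation hits
either base of the CpG.  The sampling test computes `M1 = mean(group 1)`,
draws the smaller group's size without replacement from the larger group
per replicate (default 10,000), and reports `P(M1 ≥ M2_sampled)` with ties
counting toward the probability.  Two properties matter for its use:
with equal group sizes the procedure degenerates (the subsample is the
whole larger group, so p ∈ {0, 1}), and its null p is uniform only when the
smaller group is much smaller than the larger (then the subsampled mean's
spread matches the spread of the group-mean difference).  The calibration
therefore uses a 1:20 size ratio for null checks and the study-like 1:3
ratio for effect detection.  Histograms use five ratio bins of width 20,
half-open except the last ([80, 100]).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
a human genome:

- **Reference**: first-order Markov chain; every row of the transition
  matrix is the base distribution implied by `gc_content` (default 0.40,
  human-like) except the C row, where C→G is scaled by `cpg_enrichment` and
  renormalised.  The default `cpg_enrichment = 1.0` (no depletion) reflects
  the CpG-island-rich exonic context of exome calls and keeps hybrid-motif
  density (~0.023) high enough for precise recovery tests; bulk human
  genome would be nearer 0.2–0.25.  The chain's stationary distribution
  gives a closed-form expected CpG count used as a generation oracle.
- **Mutations**: each position's sampling weight is the product of the
  multipliers `theta[motif]` over motifs whose mutable position it
  occupies on either strand (so a WRCG cytosine under
  `{"WRCG": 3, "CG": 2}` carries weight 6 — multiplicative composition is
  what makes analytic expectations computable).  Positions are drawn
  without replacement via the Gumbel top-k construction (exact for
  weight-proportional sampling without replacement); alternative alleles
  are the transition partner with probability 0.5 (the study-like
  transition:transversion balance), else a uniform transversion; sample
  ids spread uniformly over 22 synthetic patients.  Under a single planted
  multiplier θ at motif density d, the expected excess is
  `θ/(θd+1−d)`; recovery at n = 10,000 mutations lands within the binomial
  sampling band of that expectation (measured ~2–4% relative error).
- **Methylation**: per CpG, depth ~ Poisson(30) floored at 1; an
  underlying ratio from a high-methylation mixture (85% of sites ~
  N(85, 10), the rest ~ N(10, 10), clipped to [0, 100] — bisulfite data of
  gene-rich regions is bimodal and mostly methylated; the implied mean ≈ 74
  matches blood-cancer cohort scale); methylated counts are binomial at
  that ratio.  `wrcg_mutated_delta` (default 5) shifts the whole mixture
  down at mutated WRCG-context sites, so the planted group-mean difference
  equals δ away from the clipping boundaries (slightly less near them).

What the generator does **not** emulate: mutation-rate heterogeneity along
the genome beyond motif effects, clustered hypermutation, selection,
clonal structure, per-patient variation in signature mix, and sequencing
artefacts.  Passing tests therefore demonstrate correctness of the
statistics under the assumed sampling model, not robustness to every
property of real tumour data.

## Problem sizes and determinism

Default experiment sizes — 500 null datasets of 200 mutations, 10,000
mutations on a 600 kb reference for recovery, 1,000 power subsamples,
10,000 sampling-test replicates — follow the study-scale procedures while
keeping a full run in minutes on one core.  All randomness flows through
`numpy.random.Generator` seeds; every CLI command takes `--seed`, results
record it, and repeated runs are byte-identical.

## Known limitations

- Neighborhood windows are extracted per mutation; recurrent mutations
  shared across patients are kept as independent records (no
  deduplication flag applied by default).
- The Fisher test treats neighborhood positions as an independent sample;
  mutations and their windows are drawn from the same genome, so the test
  is exact only under the conditional model (the calibration experiments
  quantify the residual: none detectable at D ≈ 0.013 over 3,000 null
  datasets).
- The region-mode contrast scans plus deduplicates in memory; it is meant
  for megabase-scale scopes, not whole-genome scans in one call.
- External-cohort numbers (COSMIC, ICGC MALY-DE, follicular-lymphoma
  exomes) can only be validated when those datasets are supplied to
  `aidsig.reference.evaluate_external_targets`; the package ships the
  published summary fractions and recomputes derived ratios from them.
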