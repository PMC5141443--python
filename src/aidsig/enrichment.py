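"""Excess of mutations in a degenerate motif relative to the local DNA
neighborhood.

The statistic
-------------

For a set of somatic single-base substitutions, each carrying the sequence
window centred on it (its *DNA neighborhood*, 60 bases either side by
default), and a strand-symmetric motif pair:

* ``Fm`` — the fraction of mutations whose mutated base sits at the motif's
  mutation-prone position (on either strand): ``k_in_motif / n_mutations``.
* ``Fn`` — the frequency of motif positions among all *un-mutated* neighborhood
  positions: ``motif_positions / total_positions``.  Mutated center positions
  and masked (``N``) bases are excluded from both counts.
* ``excess = Fm / Fn`` — values above 1 mean the mutational process prefers
  the motif beyond what local base composition explains.

Significance comes from a two-sided Fisher exact test on the 2x2 table
``[mutations in/out of motif] x [neighborhood positions in/out of motif]`` and
from a one-sided Monte Carlo test that reassigns every mutation uniformly to
an un-mutated position with the same reference base inside its own window,
preserving per-window base composition and the mutation count.

With ``mask_cpg`` every base of every CpG dinucleotide in each window is
replaced by ``N`` before any counting, and mutations whose own center is
masked are dropped — this removes the CpG-driven component of C/G motif
enrichment, isolating non-CpG context preferences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple  # noqa: F401

import numpy as np
from scipy import stats

from .io import MutationRecord
from .motifs import MotifPair, encode, motif_position_mask

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class EnrichmentResult:
    """The motif-excess statistic with its contingency counts and p-values."""

    motif_name: str
    n_mutations: int
    k_in_motif: int
    motif_positions: int
    total_positions: int
    mc_reps: int = 0
    mc_p: Optional[float] = None
    fisher_p: Optional[float] = None
    seed: Optional[int] = None
    n_dropped_masked: int = 0
    bonferroni_significant: Optional[bool] = None

    @property
    def computable(self) -> bool:
        return self.total_positions > 0 and self.motif_positions > 0 and self.n_mutations > 0

    @property
    def fm(self) -> float:
        return self.k_in_motif / self.n_mutations if self.n_mutations else float("nan")

    @property
    def fn(self) -> float:
        return (
            self.motif_positions / self.total_positions
            if self.total_positions
            else float("nan")
        )

    @property
    def excess(self) -> Optional[float]:
        """Fm / Fn; ``None`` when Fn is zero (flagged non-computable)."""
        if not self.total_positions or not self.motif_positions:
            return None
        return self.fm / self.fn

    @property
    def effect_size(self) -> float:
        """Fm - Fn, the difference of fractions used by the power analysis."""
        return self.fm - self.fn


def excess_from_fractions(fm: float, fn: float) -> float:
    """The excess ratio Fm/Fn from already-computed fractions."""
    if fn <= 0:
        raise ValueError("Fn must be positive")
    return fm / fn


def mask_cpg_sequence(seq: str) -> str:
    """Replace both bases of every CG dinucleotide with ``N``."""
    chars = list(seq)
    for m in re.finditer("(?=CG)", seq):
        chars[m.start()] = "N"
        chars[m.start() + 1] = "N"
    return "".join(chars)


@dataclass
class _WindowStats:
    """Per-window counting arrays shared by the enrichment, MC and power paths.

    All arrays have one entry per retained mutation: whether its center is a
    motif position, the motif/total counts of valid (un-mutated, non-N)
    neighborhood positions, and the same-ref-base candidate fraction used by
    the Monte Carlo reassignment.
    """

    center_hit: np.ndarray  # bool
    motif_pos: np.ndarray  # int
    total_pos: np.ndarray  # int
    mc_prob: np.ndarray  # float: P(reassigned position is a motif position)
    n_no_candidate: int
    n_dropped_masked: int
    retained: List[MutationRecord]


def _mutated_positions(mutations: Sequence[MutationRecord]) -> Dict[str, Set[int]]:
    by_chrom: Dict[str, Set[int]] = {}
    for m in mutations:
        by_chrom.setdefault(m.chrom, set()).add(m.pos)
    return by_chrom


def window_stats(
    mutations: Sequence[MutationRecord],
    pair: MotifPair,
    mask_cpg: bool = False,
    mc_mode: str = "same_base",
) -> _WindowStats:
    """Count motif occupancy per neighborhood window.

    Valid neighborhood positions exclude every mutated center position of the
    dataset (any mutation falling inside the window, not just the window's
    own center), every ``N`` base, and the boundary positions whose motif
    status the window cannot determine (an occurrence placing them at the
    mutable offset would extend past the window edge; counting such
    positions as non-motif would deflate Fn and bias the Monte Carlo null
    anti-conservative, since the observed center always has full context).
    ``mc_mode`` selects the Monte Carlo candidate set: ``"same_base"``
    (default) restricts reassignment to valid positions carrying the
    mutation's reference base; ``"any_base"`` shuffles over all valid
    positions ignoring base identity.
    """
    if mc_mode not in ("same_base", "any_base"):
        raise ValueError(f"unknown mc_mode {mc_mode!r}")
    mutated = _mutated_positions(mutations)
    center_hit: List[bool] = []
    motif_counts: List[int] = []
    total_counts: List[int] = []
    mc_prob: List[float] = []
    retained: List[MutationRecord] = []
    n_no_candidate = 0
    n_dropped = 0
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    # symmetric margin inside which a position's motif status is undetermined
    k_pat = len(pair.forward.pattern)
    margin = max(pair.forward.mutable_index, k_pat - 1 - pair.forward.mutable_index)
    for rec in mutations:
        if rec.neighborhood is None or rec.center_index is None:
            raise ValueError(f"mutation {rec.chrom}:{rec.pos} has no neighborhood attached")
        seq = rec.neighborhood
        if mask_cpg:
            seq = mask_cpg_sequence(seq)
            if seq[rec.center_index] == "N":
                n_dropped += 1
                continue
        codes = encode(seq)
        mask = motif_position_mask(codes, pair)
        # genomic (1-based) position of window offset j is rec.pos - ci + j
        offset = rec.pos - rec.center_index
        mut_here = mutated.get(rec.chrom, set())
        valid = codes != 4  # N excluded
        if margin:
            valid[:margin] = False
            valid[len(seq) - margin :] = False
        if mut_here:
            window_positions = offset + np.arange(len(seq))
            valid &= ~np.isin(window_positions, list(mut_here))
        else:  # pragma: no cover - centers are always in the mutated set
            valid[rec.center_index] = False
        hit = bool(mask[rec.center_index])
        center_hit.append(hit)
        motif_counts.append(int(mask[valid].sum()))
        total_counts.append(int(valid.sum()))
        if mc_mode == "same_base":
            cand = valid & (codes == base_index[rec.ref])
        else:
            cand = valid.copy()
        # the observed arrangement must be part of the randomization support
        # (a permutation-type test that excludes the identity is
        # anti-conservative), so the window's own center is a candidate even
        # though it is excluded from the un-mutated position totals
        cand[rec.center_index] = True
        m_i = int(cand.sum())
        if m_i == 0:
            # no reassignment candidate: the mutation keeps its position
            n_no_candidate += 1
            mc_prob.append(1.0 if hit else 0.0)
        else:
            mc_prob.append(int(mask[cand].sum()) / m_i)
        retained.append(rec)
    if n_no_candidate:
        logger.info(
            "%d mutation(s) had no same-base reassignment candidate and keep "
            "their observed position in the Monte Carlo test",
            n_no_candidate,
        )
    return _WindowStats(
        center_hit=np.asarray(center_hit, dtype=bool),
        motif_pos=np.asarray(motif_counts, dtype=np.int64),
        total_pos=np.asarray(total_counts, dtype=np.int64),
        mc_prob=np.asarray(mc_prob, dtype=float),
        n_no_candidate=n_no_candidate,
        n_dropped_masked=n_dropped,
        retained=retained,
    )


def monte_carlo_pvalue(
    mc_prob: np.ndarray,
    k_observed: int,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> float:
    """One-sided Monte Carlo p with the add-one estimator.

    Each replicate reassigns every mutation independently and uniformly among
    its candidate positions and recounts the mutations landing on motif
    positions.  Because ``k_i`` of a window's ``m_i`` candidates are motif
    positions, the recount contribution of one mutation is a Bernoulli draw
    with probability ``k_i / m_i`` — sampled directly, which is exactly
    equivalent to drawing a candidate position uniformly.

    Returns ``(1 + #{replicates with k* >= k_observed}) / (reps + 1)``.
    """
    p, _ = _monte_carlo_counts(mc_prob, k_observed, reps, rng, chunk)
    return p


def _monte_carlo_counts(
    mc_prob: np.ndarray,
    k_observed: int,
    reps: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> Tuple[float, Tuple[int, int]]:
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = mc_prob.shape[0]
    greater = ties = 0
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        kstar = (rng.random((b, n)) < mc_prob[None, :]).sum(axis=1)
        greater += int((kstar > k_observed).sum())
        ties += int((kstar == k_observed).sum())
        done += b
    return (1 + greater + ties) / (reps + 1), (greater, ties)


def monte_carlo_pvalue_randomized(
    mc_prob: np.ndarray,
    k_observed: int,
    reps: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Conservative and tie-smoothed Monte Carlo p-values.

    The estimator ``(1 + #{k* >= k}) / (reps + 1)`` is deliberately
    conservative: ties between replicate and observed counts all push the
    p-value up, by about half the modal count probability.  For calibration
    diagnostics this function also returns the randomized version
    ``(#{k* > k} + U * (1 + #{k* = k})) / (reps + 1)``, which is exactly
    Uniform(0,1) when the reassignment null matches the data-generating
    process.  Inference always uses the conservative estimator.
    """
    p, (greater, ties) = _monte_carlo_counts(mc_prob, k_observed, reps, rng)
    p_rand = (greater + rng.random() * (1 + ties)) / (reps + 1)
    return p, p_rand


def fisher_pvalue(k: int, n: int, m: int, t: int) -> float:
    """Two-sided Fisher exact p on [[k, n-k], [m, t-m]]."""
    return float(stats.fisher_exact([[k, n - k], [m, t - m]], alternative="two-sided")[1])


def fisher_pvalue_hypergeom(k: int, n: int, m: int, t: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Sums, over the conditional support given the table margins, the
    probabilities of all tables whose probability does not exceed the
    observed table's (with the customary relative tolerance for float ties).
    Serves as an implementation-independent cross-check of
    :func:`fisher_pvalue`.
    """
    M, K, N = n + t, k + m, n
    dist = stats.hypergeom(M, K, N)
    lo, hi = int(max(0, K - (M - N))), int(min(K, N))
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    return float(pmf[pmf <= pmf[k - lo] * (1 + 1e-7)].sum())


def fisher_pvalue_randomized(
    k: int, n: int, m: int, t: int, rng: np.random.Generator
) -> float:
    """Tie-smoothed (randomized) two-sided Fisher p, for calibration checks.

    A discrete test's exact p-value is sub-uniform with atoms, so its raw
    distribution cannot match a continuous uniform even when computed
    perfectly.  The randomized version draws uniformly between the largest
    attainable p strictly below the observed one and the observed p itself;
    under the hypergeometric null it is exactly Uniform(0,1) if and only if
    the p-value function is correct, making it the appropriate statistic for
    uniformity diagnostics.  Never used for inference.
    """
    M, K, N = n + t, k + m, n
    dist = stats.hypergeom(M, K, N)
    lo, hi = int(max(0, K - (M - N))), int(min(K, N))
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    tol = 1 + 1e-7
    p_obs = float(pmf[pmf <= pmf[k - lo] * tol].sum())
    attainable = np.array([pmf[pmf <= pmf[j] * tol].sum() for j in range(support.size)])
    below = attainable[attainable < p_obs / tol]
    p_prev = float(below.max()) if below.size else 0.0
    return p_prev + rng.random() * (p_obs - p_prev)


def compute_enrichment(
    mutations: Sequence[MutationRecord],
    pair: MotifPair,
    mask_cpg: bool = False,
    mc_reps: int = 1000,
    rng_seed: Optional[int] = None,
    mc_mode: str = "same_base",
    motif_name: Optional[str] = None,
) -> EnrichmentResult:
    """Compute the motif-excess statistic for one motif pair on one dataset.

    ``mc_reps=0`` disables the Monte Carlo test (``mc_p`` stays ``None``).
    Raises ``ValueError`` on an empty mutation set; an ``Fn`` of zero is
    returned flagged non-computable rather than raising.
    """
    if not mutations:
        raise ValueError("empty mutation set")
    ws = window_stats(mutations, pair, mask_cpg=mask_cpg, mc_mode=mc_mode)
    name = motif_name if motif_name is not None else pair.name
    n = len(ws.retained)
    if n == 0:
        return EnrichmentResult(
            motif_name=name,
            n_mutations=0,
            k_in_motif=0,
            motif_positions=0,
            total_positions=0,
            n_dropped_masked=ws.n_dropped_masked,
            seed=rng_seed,
        )
    k = int(ws.center_hit.sum())
    m = int(ws.motif_pos.sum())
    t = int(ws.total_pos.sum())
    result = EnrichmentResult(
        motif_name=name,
        n_mutations=n,
        k_in_motif=k,
        motif_positions=m,
        total_positions=t,
        n_dropped_masked=ws.n_dropped_masked,
        seed=rng_seed,
        mc_reps=mc_reps,
    )
    if not result.computable:
        return result
    result.fisher_p = fisher_pvalue(k, n, m, t)
    if mc_reps > 0:
        rng = np.random.default_rng(rng_seed)
        result.mc_p = monte_carlo_pvalue(ws.mc_prob, k, mc_reps, rng)
    return result


def monte_carlo_test(
    mutations: Sequence[MutationRecord],
    pair: MotifPair,
    reps: int,
    rng_seed: Optional[int] = None,
    mask_cpg: bool = False,
    mc_mode: str = "same_base",
) -> float:
    """Standalone one-sided Monte Carlo test (see :func:`monte_carlo_pvalue`)."""
    ws = window_stats(mutations, pair, mask_cpg=mask_cpg, mc_mode=mc_mode)
    k = int(ws.center_hit.sum())
    rng = np.random.default_rng(rng_seed)
    return monte_carlo_pvalue(ws.mc_prob, k, reps, rng)


# ---------------------------------------------------------------------------
# Mutation spectrum
# ---------------------------------------------------------------------------

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class SpectrumSummary:
    """Tallies of substitution types, strand-symmetric where noted."""

    counts: Dict[str, int]  # all 12 raw ref>alt types
    normalized_counts: Dict[str, int]  # 6 pyrimidine-based classes
    transitions: int
    transversions: int
    at_gc: int  # mutations at G:C pairs
    at_at: int  # mutations at A:T pairs

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    @property
    def gc_at_ratio(self) -> Optional[float]:
        return self.at_gc / self.at_at if self.at_at else None


def normalize_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-based class: G>A is reported as C>T, etc."""
    if ref in _PURINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum_summary(mutations: Sequence[MutationRecord]) -> SpectrumSummary:
    if not mutations:
        raise ValueError("empty mutation set")
    counts: Dict[str, int] = {}
    norm: Dict[str, int] = {}
    transitions = transversions = gc = at = 0
    for m in mutations:
        key = f"{m.ref}>{m.alt}"
        counts[key] = counts.get(key, 0) + 1
        nkey = normalize_substitution(m.ref, m.alt)
        norm[nkey] = norm.get(nkey, 0) + 1
        if (m.ref, m.alt) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
        if m.ref in ("C", "G"):
            gc += 1
        else:
            at += 1
    return SpectrumSummary(
        counts=counts,
        normalized_counts=norm,
        transitions=transitions,
        transversions=transversions,
        at_gc=gc,
        at_at=at,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni_flags(pvalues: Sequence[Optional[float]], alpha: float = 0.05) -> List[bool]:
    """Significance flags under Bonferroni: p <= alpha / m over m tests.

    ``None`` p-values (non-computable results) count toward ``m`` but are
    never significant.
    """
    m = len(pvalues)
    if m < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / m
    return [p is not None and p <= threshold for p in pvalues]


def bonferroni(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> List[EnrichmentResult]:
    """Copy of ``results`` with ``bonferroni_significant`` set from fisher_p."""
    flags = bonferroni_flags([r.fisher_p for r in results], alpha=alpha)
    return [replace(r, bonferroni_significant=f) for r, f in zip(results, flags)]
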