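"""Association between CpG methylation ratios and the hybrid WRCG motif.

CpG positions measured by bisulfite sequencing carry a methylation ratio
(100 x methylated reads / total reads).  After a read-depth filter (strictly
more than nine reads), each CpG is classified by its sequence context —
inside a WRCG/CGYW occurrence (either strand) versus a control CpG context
(YCG/SNCG) — and flagged when a somatic mutation coincides with either base
of the CpG.  The question: are mutated WRCG-context CpGs less methylated than
mutated control CpGs?

The comparison is a sampling test: with M1 the mean ratio of the smaller
group, values are repeatedly drawn without replacement from the larger group
down to the smaller group's size, and ``P(M1 >= M2_sampled)`` is estimated
over the replicates (ties count toward the probability).  Small values mean
group 1 is significantly *less* methylated.  Histograms over five ratio bins
of width 20 (last bin closed at 100) summarize the two distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .contrast import classify_prefix, _COMP
from .io import MethylationSite, MutationRecord, as_reference

#: read-depth filter: keep sites with strictly more than this many reads
MIN_READS_EXCLUSIVE = 9

BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
BIN_LABELS = ("[0,20)", "[20,40)", "[40,60)", "[60,80)", "[80,100]")


def filter_by_depth(
    sites: Sequence[MethylationSite], min_reads_exclusive: int = MIN_READS_EXCLUSIVE
) -> List[MethylationSite]:
    """Keep sites with total_reads strictly greater than ``min_reads_exclusive``."""
    return [s for s in sites if s.total_reads > min_reads_exclusive]


def classify_context(
    sites: Sequence[MethylationSite],
    reference,
    mutations: Sequence[MutationRecord] = (),
) -> List[MethylationSite]:
    """Tag each site with its motif context and mutation coincidence.

    Context is ``"WRCG"`` when the site's CpG sits inside a WRCG/CGYW
    occurrence on either strand, ``"control"`` when it is classifiable but
    only as YCG/SNCG on every classifiable strand, and ``"other"`` when no
    orientation has two defined flanking bases (such sites are excluded
    downstream).  A site is ``mutated`` when a dataset mutation falls on
    either base of the CpG.  Sites whose reference dinucleotide is not CG are
    tagged ``"other"``.
    """
    ref = as_reference(reference)
    mutated_positions: Set[Tuple[str, int]] = {(m.chrom, m.pos) for m in mutations}
    out: List[MethylationSite] = []
    for site in sites:
        context = "other"
        if site.chrom in ref:
            clen = ref.length(site.chrom)
            pos0 = site.pos - 1
            start = max(0, pos0 - 2)
            end = min(clen, pos0 + 4)
            local = ref.fetch(site.chrom, start, end)

            def get(i: int, _off=start, _seq=local):
                j = i - _off
                return _seq[j] if 0 <= j < len(_seq) else None

            if get(pos0) == "C" and get(pos0 + 1) == "G":
                classes = []
                b1, b2 = get(pos0 - 2), get(pos0 - 1)
                if b1 is not None and b2 is not None:
                    c = classify_prefix(b1, b2)
                    if c is not None:
                        classes.append(c)
                d1, d2 = get(pos0 + 3), get(pos0 + 2)
                if d1 in _COMP and d2 in _COMP:
                    c = classify_prefix(_COMP[d1], _COMP[d2])
                    if c is not None:
                        classes.append(c)
                if classes:
                    context = "WRCG" if any(classes) else "control"
        mutated = (site.chrom, site.pos) in mutated_positions or (
            site.chrom,
            site.pos + 1,
        ) in mutated_positions
        out.append(replace(site, context=context, mutated=mutated))
    return out


def histogram_bins(ratios: Sequence[float]) -> np.ndarray:
    """Fractions over the five ratio bins [0,20), ..., [80,100].

    Raises on ratios outside [0, 100].
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("no ratios to bin")
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("methylation ratios must lie in [0, 100]")
    counts, _ = np.histogram(arr, bins=BIN_EDGES)
    return counts / arr.size


@dataclass
class MethylationComparison:
    """Group means, sampling-test p, and per-group histogram fractions."""

    m1: float
    m2: float
    n1: int
    n2: int
    p_value: float
    reps: int
    histogram1: np.ndarray
    histogram2: np.ndarray
    seed: Optional[int] = None


def sampling_mean_test(
    group1_ratios: Sequence[float],
    group2_ratios: Sequence[float],
    reps: int = 10000,
    rng_seed: Optional[int] = None,
) -> MethylationComparison:
    """Estimate P(M1 >= M2_sampled) by size-matched subsampling.

    M1 is the mean of group 1 and M2 of group 2.  Per replicate, the larger
    group is sampled without replacement down to the smaller group's size and
    its mean recorded; the p-value is the share of replicates whose sampled
    mean of the *other* group falls on the M1-or-above side — concretely,
    when group 2 is larger, ``#{M1 >= mean(sample from group2)} / reps``;
    when group 1 is larger, ``#{mean(sample from group1) >= M2} / reps``.
    Ties count toward the probability.
    """
    g1 = np.asarray(group1_ratios, dtype=float)
    g2 = np.asarray(group2_ratios, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    m1 = float(g1.mean())
    m2 = float(g2.mean())
    rng = np.random.default_rng(rng_seed)
    if g1.size <= g2.size:
        larger, n_small = g2, g1.size
        def success(sampled_mean: np.ndarray) -> np.ndarray:
            return m1 >= sampled_mean
    else:
        larger, n_small = g1, g2.size
        def success(sampled_mean: np.ndarray) -> np.ndarray:
            return sampled_mean >= m2
    count = 0
    chunk = max(1, min(reps, int(2e6 // max(1, larger.size))))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        # vectorized without-replacement draws: argpartition of uniform keys
        keys = rng.random((b, larger.size))
        idx = np.argpartition(keys, n_small - 1, axis=1)[:, :n_small]
        means = larger[idx].mean(axis=1)
        count += int(np.count_nonzero(success(means)))
        done += b
    p = count / reps
    return MethylationComparison(
        m1=m1,
        m2=m2,
        n1=int(g1.size),
        n2=int(g2.size),
        p_value=p,
        reps=reps,
        histogram1=histogram_bins(g1),
        histogram2=histogram_bins(g2),
        seed=rng_seed,
    )


def compare_mutated_contexts(
    sites: Sequence[MethylationSite],
    reps: int = 10000,
    rng_seed: Optional[int] = None,
    require_mutated: bool = True,
) -> MethylationComparison:
    """Sampling test of WRCG-context vs control-context CpG methylation.

    With ``require_mutated`` (default) only sites coinciding with a somatic
    mutation enter the comparison — the mutation-position analysis; without
    it, all classified sites are compared — the mutation-agnostic variant.
    Sites must already be depth-filtered and context-classified.
    """
    pool = [s for s in sites if s.context in ("WRCG", "control")]
    if require_mutated:
        pool = [s for s in pool if s.mutated]
    g1 = [s.ratio for s in pool if s.context == "WRCG"]
    g2 = [s.ratio for s in pool if s.context == "control"]
    if not g1 or not g2:
        raise ValueError("a comparison group is empty after filtering")
    return sampling_mean_test(g1, g2, reps=reps, rng_seed=rng_seed)
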