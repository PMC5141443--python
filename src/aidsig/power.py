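"""Subsampling power analysis for motif-enrichment effect sizes.

A small mutation set (e.g. somatic mutations from normal tissue) may show no
motif enrichment simply because it is small.  The procedure here decides
whether that absence is informative: draw many size-matched subsamples from a
large *positive* dataset (one with established enrichment), compute the
effect size — the difference ``Fm - Fn`` between the fraction of mutations in
the motif and the motif frequency in the neighborhoods — for every subsample,
and report the share of subsample effects strictly greater than the small
dataset's effect.  A share near 1 means even enrichment-positive data of this
size would usually show a larger effect, so the small dataset's null result
is unlikely to be a sample-size artifact.

Subsampling is without replacement; each subsample's effect uses that
subsample's own neighborhoods (its ``Fn`` varies accordingly).  Ties count as
not exceeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .enrichment import EnrichmentResult, compute_enrichment, window_stats
from .io import MutationRecord
from .motifs import MotifPair


def effect_size(result: EnrichmentResult) -> float:
    """Fm - Fn (difference of fractions)."""
    return result.effect_size


@dataclass
class PowerResult:
    """Outcome of the size-matched subsampling comparison."""

    reference_effect: float
    n_subsample: int
    reps: int
    exceed_fraction: float
    subsample_effects: np.ndarray  # per-replicate effects, retained for audit
    seed: Optional[int] = None


def subsample_effects(
    positive_mutations: Sequence[MutationRecord],
    pair: MotifPair,
    n_subsample: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Effect sizes of ``reps`` without-replacement subsamples of the positive set."""
    ws = window_stats(positive_mutations, pair)
    n = len(ws.retained)
    if n_subsample > n:
        raise ValueError(f"subsample size {n_subsample} exceeds positive set size {n}")
    hits = ws.center_hit.astype(np.int64)
    effects = np.empty(reps, dtype=float)
    for r in range(reps):
        idx = rng.choice(n, size=n_subsample, replace=False)
        fm = hits[idx].sum() / n_subsample
        fn = ws.motif_pos[idx].sum() / ws.total_pos[idx].sum()
        effects[r] = fm - fn
    return effects


def subsample_power(
    positive_mutations: Sequence[MutationRecord],
    reference_mutations: Sequence[MutationRecord],
    pair: MotifPair,
    reps: int = 1000,
    rng_seed: Optional[int] = None,
) -> PowerResult:
    """Share of size-matched positive subsamples whose effect exceeds the reference's.

    ``exceed_fraction = #{effect_subsample > effect_reference} / reps`` — the
    strict inequality measures exceedance from the positive side, with ties
    counted as not exceeding.
    """
    n_ref = len(reference_mutations)
    n_pos = len(positive_mutations)
    if n_ref > n_pos:
        raise ValueError(
            f"reference set ({n_ref}) larger than positive set ({n_pos}); "
            "the procedure subsamples the positive set down to the reference size"
        )
    ref_result = compute_enrichment(reference_mutations, pair, mc_reps=0)
    ref_effect = ref_result.effect_size
    rng = np.random.default_rng(rng_seed)
    effects = subsample_effects(positive_mutations, pair, n_ref, reps, rng)
    exceed = float(np.count_nonzero(effects > ref_effect) / reps)
    return PowerResult(
        reference_effect=ref_effect,
        n_subsample=n_ref,
        reps=reps,
        exceed_fraction=exceed,
        subsample_effects=effects,
        seed=rng_seed,
    )
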