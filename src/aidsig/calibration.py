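"""Self-calibration experiments: null uniformity, planted-parameter recovery,
power-procedure checks.

These routines generate synthetic datasets with the package's own generator
and push them through the analysis stages, returning the raw per-replicate
measurements so tests (and the reproduction script) can assert calibration:

* :func:`null_pvalue_calibration` — p-value uniformity and type-I error of
  the Fisher and Monte Carlo tests on motif-indifferent data.  The default
  motif is ``WA``, the densest motif of the catalog (about a quarter of all
  positions): exact p-values of a discrete statistic carry an atom at 1 of
  the size of the modal table's probability, and the densest motif keeps
  that discreteness well below the resolution of a uniformity check at a
  few hundred datasets.  Type-I error is motif-agnostic.
* :func:`planted_theta_recovery` — enrichment recovery against the analytic
  expectation ``theta / (theta*d + 1 - d)`` for a planted rate multiplier
  ``theta`` at motif density ``d``.
* :func:`power_calibration` — the subsampling power procedure on generator
  pairs with and without planted enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .enrichment import (
    fisher_pvalue,
    fisher_pvalue_randomized,
    monte_carlo_pvalue_randomized,
    window_stats,
)
from .contrast import contrast_on_neighborhoods
from .io import attach_neighborhoods
from .motifs import default_catalog, motif_position_mask
from .power import subsample_power
from .simulate import SyntheticTruth, generate_mutations, generate_reference


@dataclass
class NullCalibration:
    fisher_p: np.ndarray
    fisher_p_randomized: np.ndarray
    mc_p: np.ndarray
    mc_p_randomized: np.ndarray

    def type_i_error(self, alpha: float = 0.05) -> Tuple[float, float]:
        return (
            float((self.fisher_p <= alpha).mean()),
            float((self.mc_p <= alpha).mean()),
        )


def null_pvalue_calibration(
    n_datasets: int = 500,
    n_mutations: int = 200,
    mc_reps: int = 199,
    genome_length: int = 30_000,
    motif: str = "WA",
    seed: int = 0,
) -> NullCalibration:
    """Fisher and MC p-values over independent motif-indifferent datasets.

    Each dataset draws its own reference sequence and places ``n_mutations``
    uniformly on it (no motif preference), so the p-values are independent
    draws under a true null and the empirical rejection rate has plain
    binomial sampling variance.
    Alongside the raw Fisher p, the tie-smoothed (randomized) Fisher p is
    recorded: the raw exact p of a discrete table is sub-uniform by
    construction (its atom at 1 equals the modal table's probability, about
    ``1/sqrt(2*pi*n*d*(1-d))``), so continuous-uniformity diagnostics apply
    to the randomized version, which is exactly Uniform(0,1) under the
    test's null model iff the p-value function is correct.
    """
    pair = default_catalog()[motif]
    truth = SyntheticTruth(genome_length=genome_length, n_mutations=n_mutations, theta={})
    rng = np.random.default_rng(seed)
    fisher = np.empty(n_datasets)
    fisher_rand = np.empty(n_datasets)
    mc = np.empty(n_datasets)
    mc_rand = np.empty(n_datasets)
    for i in range(n_datasets):
        reference = generate_reference(truth, rng)
        contigs = {"chr1": reference}
        muts = generate_mutations(reference, truth, rng)
        muts = attach_neighborhoods(muts, contigs)
        ws = window_stats(muts, pair)
        k = int(ws.center_hit.sum())
        n = len(ws.retained)
        m = int(ws.motif_pos.sum())
        t = int(ws.total_pos.sum())
        fisher[i] = fisher_pvalue(k, n, m, t)
        fisher_rand[i] = fisher_pvalue_randomized(k, n, m, t, rng)
        mc[i], mc_rand[i] = monte_carlo_pvalue_randomized(ws.mc_prob, k, mc_reps, rng)
    return NullCalibration(
        fisher_p=fisher,
        fisher_p_randomized=fisher_rand,
        mc_p=mc,
        mc_p_randomized=mc_rand,
    )


@dataclass
class ThetaRecovery:
    observed_excess: float
    expected_excess: float
    motif_density: float
    contrast_p: Optional[float]
    fisher_p: Optional[float]

    @property
    def relative_error(self) -> float:
        return abs(self.observed_excess - self.expected_excess) / self.expected_excess


def analytic_excess(theta: float, density: float) -> float:
    """Expected Fm/Fn when one motif class carries rate multiplier ``theta``.

    With motif-position density ``d``, a mutation lands in the motif with
    probability ``theta*d / (theta*d + 1 - d)`` while the neighborhood
    frequency stays ``d``; the ratio is ``theta / (theta*d + 1 - d)``.
    """
    return theta / (theta * density + 1 - density)


def planted_theta_recovery(
    theta: float = 3.0,
    motif: str = "WRCG",
    n_mutations: int = 10_000,
    genome_length: int = 600_000,
    seed: int = 0,
    extra_theta: Optional[Dict[str, float]] = None,
    run_contrast: bool = True,
) -> ThetaRecovery:
    """Generate data with a planted multiplier and measure the recovered excess.

    The analytic expectation uses the realized motif-position density of the
    generated reference.  ``extra_theta`` plants additional multipliers (the
    analytic formula then no longer applies and only the contrast is
    meaningful).
    """
    pair = default_catalog()[motif]
    full_theta = {motif: theta}
    if extra_theta:
        full_theta.update(extra_theta)
    truth = SyntheticTruth(
        genome_length=genome_length, n_mutations=n_mutations, theta=full_theta
    )
    rng = np.random.default_rng(seed)
    reference = generate_reference(truth, rng)
    density = float(motif_position_mask(reference, pair).mean())
    muts = generate_mutations(reference, truth, rng)
    muts = attach_neighborhoods(muts, {"chr1": reference})
    ws = window_stats(muts, pair)
    k = int(ws.center_hit.sum())
    n = len(ws.retained)
    m = int(ws.motif_pos.sum())
    t = int(ws.total_pos.sum())
    fm = k / n
    fn = m / t
    contrast_p = None
    if run_contrast:
        contrast_p = contrast_on_neighborhoods(muts).fisher_p
    return ThetaRecovery(
        observed_excess=fm / fn,
        expected_excess=analytic_excess(theta, density),
        motif_density=density,
        contrast_p=contrast_p,
        fisher_p=fisher_pvalue(k, n, m, t),
    )


@dataclass
class MethylationCalibration:
    planted_p: float
    planted_m1: float
    planted_m2: float
    null_p: np.ndarray


def methylation_calibration(
    delta: float = 5.0,
    n_small: int = 3_000,
    n_large: int = 9_000,
    reps: int = 2_000,
    n_null_trials: int = 200,
    null_n_small: int = 150,
    null_n_large: int = 3_000,
    null_reps: int = 400,
    seed: int = 0,
) -> MethylationCalibration:
    """Sampling-mean test on planted and null methylation groups.

    Groups are drawn from the generator's methylation mixture; the planted
    run depresses group 1's mean by ``delta`` and keeps the study's roughly
    1:3 proportion of hybrid-motif to control CpG positions.  The null p of
    this sampling test is uniform only in the regime where the smaller group
    is much smaller than the larger (the subsampled mean's spread then
    matches the spread of the group-mean difference; for equal sizes the
    procedure degenerates — subsampling the larger group down to an equal
    size returns the whole group), so the null trials use a 1:20 ratio.
    """
    from .methylation import sampling_mean_test
    from .simulate import sample_ratios

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    g1 = sample_ratios(n_small, truth, rng, delta=delta)
    g2 = sample_ratios(n_large, truth, rng, delta=0.0)
    sub = rng.integers(0, 2**31 - 1, size=n_null_trials + 1)
    planted = sampling_mean_test(g1, g2, reps=reps, rng_seed=int(sub[0]))
    null_p = np.empty(n_null_trials)
    for i in range(n_null_trials):
        h1 = sample_ratios(null_n_small, truth, rng, delta=0.0)
        h2 = sample_ratios(null_n_large, truth, rng, delta=0.0)
        null_p[i] = sampling_mean_test(
            h1, h2, reps=null_reps, rng_seed=int(sub[i + 1])
        ).p_value
    return MethylationCalibration(
        planted_p=planted.p_value,
        planted_m1=planted.m1,
        planted_m2=planted.m2,
        null_p=null_p,
    )


@dataclass
class PowerCalibration:
    mean_exceed_fraction_null: float
    null_exceed_fractions: np.ndarray
    exceed_fraction_enriched: float


def power_calibration(
    theta: float = 3.0,
    motif: str = "WRC",
    n_positive: int = 2_000,
    n_reference: int = 50,
    reps: int = 1000,
    null_reps: int = 200,
    n_null_trials: int = 30,
    genome_length: int = 250_000,
    seed: int = 0,
) -> PowerCalibration:
    """Exceedance fractions of the power procedure in two regimes.

    *null*: positive and reference sets come from the same motif-indifferent
    generator.  A single reference draw gives an exceedance that is itself
    approximately uniform (it is one empirical tail probability), so the
    exchangeability statement — the exceedance probability is 1/2 — is
    checked on the *mean* over independent reference draws, the
    Mann-Whitney-type estimate.
    *enriched*: the positive set carries a planted ``theta`` while the
    reference does not — size-matched positive subsamples then beat the
    reference's effect nearly always.
    """
    pair = default_catalog()[motif]
    rng = np.random.default_rng(seed)
    null_truth = SyntheticTruth(genome_length=genome_length, n_mutations=n_positive, theta={})
    reference = generate_reference(null_truth, rng)
    contigs = {"chr1": reference}

    def draw(n: int, theta_map: Dict[str, float]):
        truth = SyntheticTruth(
            genome_length=genome_length, n_mutations=n, theta=theta_map
        )
        muts = generate_mutations(reference, truth, rng)
        return attach_neighborhoods(muts, contigs)

    sub = rng.integers(0, 2**31 - 1, size=n_null_trials + 1)
    pos_null = draw(n_positive, {})
    null_fracs = np.empty(n_null_trials)
    for i in range(n_null_trials):
        ref_null = draw(n_reference, {})
        null_fracs[i] = subsample_power(
            pos_null, ref_null, pair, reps=null_reps, rng_seed=int(sub[i])
        ).exceed_fraction
    pos_enriched = draw(n_positive, {motif: theta})
    ref_flat = draw(n_reference, {})
    enr_res = subsample_power(
        pos_enriched, ref_flat, pair, reps=reps, rng_seed=int(sub[-1])
    )
    return PowerCalibration(
        mean_exceed_fraction_null=float(null_fracs.mean()),
        null_exceed_fractions=null_fracs,
        exceed_fraction_enriched=enr_res.exceed_fraction,
    )
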