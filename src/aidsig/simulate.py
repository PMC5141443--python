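"""Synthetic data with planted motif enrichment and methylation structure.

The generator provides ground truth for every analysis stage:

* a reference sequence from a first-order Markov chain with controlled GC
  content and a CpG-dinucleotide frequency multiplier (``cpg_enrichment``)
  over what base composition alone would give;
* somatic single-base substitutions whose per-position sampling weight is the
  product of the rate multipliers (``theta``) of every motif whose
  mutation-prone position the site occupies, on either strand — so a WRCG
  cytosine planted with ``theta = {"WRCG": 3, "CG": 2}`` carries weight 6;
* per-CpG methylation tables from a high-methylation mixture (a mostly
  methylated compartment plus a small unmethylated one, as bisulfite data of
  gene-rich regions typically shows), with an optional mean depression
  ``wrcg_mutated_delta`` at mutated WRCG-context sites, and binomially
  sampled read counts at Poisson depth.

Everything is bit-reproducible given the truth parameters and a seed, and the
truth object serializes to JSON/YAML so any fixture can be rebuilt.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contrast import _COMP, classify_prefix
from .io import MutationRecord, MethylationSite, attach_neighborhoods
from .motifs import MotifPair, default_catalog, motif_position_mask

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters; the generator's single source of configuration.

    ``theta`` maps catalog motif names to rate multipliers at their mutable
    positions (1.0 everywhere = null).  Methylation ratios come from a
    two-component normal mixture truncated to [0, 100]; ``wrcg_mutated_delta``
    shifts the whole mixture down at mutated WRCG-context CpGs.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.4
    cpg_enrichment: float = 1.0
    theta: Dict[str, float] = field(default_factory=dict)
    n_mutations: int = 13_000
    n_samples: int = 22
    transition_prob: float = 0.5
    meth_high_weight: float = 0.85
    meth_high_mean: float = 85.0
    meth_low_mean: float = 10.0
    meth_sd: float = 10.0
    depth_mean: float = 30.0
    wrcg_mutated_delta: float = 5.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be non-negative")
        if any(v <= 0 for v in self.theta.values()):
            raise ValueError("rate multipliers must be positive")
        if not 0 <= self.transition_prob <= 1:
            raise ValueError("transition_prob must lie in [0, 1]")
        if not 0 <= self.meth_high_weight <= 1:
            raise ValueError("meth_high_weight must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

def transition_matrix(truth: SyntheticTruth) -> np.ndarray:
    """Row-stochastic base-transition matrix of the reference chain.

    Every row is the stationary-free base distribution pi except the C row,
    where the C->G probability is scaled by ``cpg_enrichment`` and the row
    renormalized.
    """
    gc = truth.gc_content
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = np.tile(pi, (4, 1))
    row_c = pi.copy()
    row_c[2] *= truth.cpg_enrichment
    T[1] = row_c / row_c.sum()
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state row-stochastic matrix."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    mu = np.real(vecs[:, i])
    mu = np.abs(mu)
    return mu / mu.sum()


def expected_cpg_count(truth: SyntheticTruth) -> float:
    """Expected number of CG dinucleotides in a generated sequence (chain oracle)."""
    T = transition_matrix(truth)
    mu = stationary_distribution(T)
    return (truth.genome_length - 1) * mu[1] * T[1, 2]


def generate_reference(
    truth: SyntheticTruth, rng: Optional[np.random.Generator] = None
) -> str:
    """One contig from the first-order chain; deterministic under seed."""
    rng = rng if rng is not None else np.random.default_rng(truth.rng_seed)
    T = transition_matrix(truth)
    cum = np.cumsum(T, axis=1)
    cum[:, 3] = 1.0  # guard against rounding
    L = truth.genome_length
    u = rng.random(L)
    pi = np.cumsum(np.array([(1 - truth.gc_content) / 2, truth.gc_content / 2,
                             truth.gc_content / 2, (1 - truth.gc_content) / 2]))
    out = np.empty(L, dtype=np.uint8)
    # first base from the composition distribution
    out[0] = int(np.searchsorted(pi, u[0], side="right"))
    c0, c1, c2 = cum[:, 0], cum[:, 1], cum[:, 2]
    prev = out[0]
    for i in range(1, L):
        ui = u[i]
        if ui < c0[prev]:
            prev = 0
        elif ui < c1[prev]:
            prev = 1
        elif ui < c2[prev]:
            prev = 2
        else:
            prev = 3
        out[i] = prev
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def position_weights(
    sequence: str,
    theta: Dict[str, float],
    catalog: Optional[Dict[str, MotifPair]] = None,
) -> np.ndarray:
    """Per-position sampling weights: product of multipliers of matching motifs."""
    catalog = catalog if catalog is not None else default_catalog()
    w = np.ones(len(sequence), dtype=float)
    for name, multiplier in theta.items():
        if name not in catalog:
            raise KeyError(f"unknown motif {name!r} in theta")
        mask = motif_position_mask(sequence, catalog[name])
        w[mask] *= multiplier
    return w


def generate_mutations(
    reference: str,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chr1",
    catalog: Optional[Dict[str, MotifPair]] = None,
    n_mutations: Optional[int] = None,
) -> List[MutationRecord]:
    """Sample substitutions without replacement, weight-proportionally.

    Sampling without replacement proportional to weights uses the Gumbel
    top-k construction (equivalent to sequential weighted draws).  Alt bases
    are the transition partner with probability ``transition_prob``, else one
    of the two transversions uniformly.  Sample ids are assigned uniformly
    over ``n_samples`` synthetic patients.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.rng_seed)
    n = truth.n_mutations if n_mutations is None else n_mutations
    L = len(reference)
    if n > L:
        raise ValueError(f"cannot place {n} mutations on {L} positions")
    w = position_weights(reference, truth.theta, catalog)
    keys = np.log(w) + rng.gumbel(size=L)
    positions0 = np.sort(np.argpartition(-keys, n - 1)[:n]) if n < L else np.arange(L)
    u_alt = rng.random(n)
    u_tv = rng.random(n)
    u_sample = rng.integers(0, truth.n_samples, size=n)
    records: List[MutationRecord] = []
    for j, p0 in enumerate(positions0):
        ref = reference[p0]
        if u_alt[j] < truth.transition_prob:
            alt = _TRANSITION[ref]
        else:
            tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
            alt = tv[0] if u_tv[j] < 0.5 else tv[1]
        records.append(
            MutationRecord(
                chrom=chrom,
                pos=int(p0) + 1,
                ref=ref,
                alt=alt,
                sample_id=f"P{int(u_sample[j]) + 1:02d}",
            )
        )
    return records


def generate_dataset(
    truth: SyntheticTruth,
    rng_seed: Optional[int] = None,
    flank: int = 60,
    chrom: str = "chr1",
) -> Tuple[str, List[MutationRecord]]:
    """Reference plus neighborhood-attached mutations in one call."""
    seed = rng_seed if rng_seed is not None else truth.rng_seed
    rng = np.random.default_rng(seed)
    reference = generate_reference(truth, rng)
    mutations = generate_mutations(reference, truth, rng, chrom=chrom)
    mutations = attach_neighborhoods(mutations, {chrom: reference}, flank=flank)
    return reference, mutations


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def sample_ratios(
    n: int,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    delta: float = 0.0,
) -> np.ndarray:
    """Draw ``n`` methylation ratios from the mixture, mean-shifted by ``-delta``.

    The shift applies to both mixture components before clipping to [0, 100],
    so (away from the boundaries) group means differ by ``delta``.
    """
    high = rng.random(n) < truth.meth_high_weight
    means = np.where(high, truth.meth_high_mean, truth.meth_low_mean) - delta
    ratios = rng.normal(means, truth.meth_sd)
    return np.clip(ratios, 0.0, 100.0)


def _cpg_contexts(reference: str) -> List[Tuple[int, str]]:
    """(0-based C position, context) of every CpG; context WRCG/control/other."""
    out: List[Tuple[int, str]] = []
    L = len(reference)
    for p0 in range(L - 1):
        if reference[p0] == "C" and reference[p0 + 1] == "G":
            classes = []
            if p0 >= 2:
                c = classify_prefix(reference[p0 - 2], reference[p0 - 1])
                if c is not None:
                    classes.append(c)
            if p0 + 3 < L:
                c = classify_prefix(_COMP[reference[p0 + 3]], _COMP[reference[p0 + 2]])
                if c is not None:
                    classes.append(c)
            if classes:
                out.append((p0, "WRCG" if any(classes) else "control"))
            else:
                out.append((p0, "other"))
    return out


def generate_methylation(
    reference: str,
    mutations: Sequence[MutationRecord],
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chr1",
) -> List[MethylationSite]:
    """Per-CpG methylation records with the planted context effect.

    Mutated WRCG-context CpGs (a mutation at either base of the CpG) have
    their mixture mean depressed by ``wrcg_mutated_delta``; read depth is
    Poisson(``depth_mean``) floored at 1; methylated counts are binomial at
    the drawn underlying ratio.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.rng_seed)
    mut_positions = {m.pos for m in mutations if m.chrom == chrom}
    contexts = _cpg_contexts(reference)
    n = len(contexts)
    if n == 0:
        return []
    mutated = np.array(
        [(p0 + 1) in mut_positions or (p0 + 2) in mut_positions for p0, _ in contexts]
    )
    is_wrcg = np.array([ctx == "WRCG" for _, ctx in contexts])
    deltas = np.where(mutated & is_wrcg, truth.wrcg_mutated_delta, 0.0)
    high = rng.random(n) < truth.meth_high_weight
    means = np.where(high, truth.meth_high_mean, truth.meth_low_mean) - deltas
    ratios = np.clip(rng.normal(means, truth.meth_sd), 0.0, 100.0)
    depth = np.maximum(1, rng.poisson(truth.depth_mean, size=n))
    meth = rng.binomial(depth, ratios / 100.0)
    return [
        MethylationSite(
            chrom=chrom,
            pos=int(p0) + 1,
            methylated_reads=int(meth[i]),
            total_reads=int(depth[i]),
        )
        for i, (p0, _ctx) in enumerate(contexts)
    ]
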