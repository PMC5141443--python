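"""Hybrid-motif contrast: WRCG/CGYW versus CpG contexts lacking WRC.

Every CpG dinucleotide whose cytosine has two defined upstream bases can be
classified, per orientation, as exactly one of

* target — ``WRCG`` (the two bases 5' of the CG are ``W`` then ``R``), the
  hybrid of the AID deaminase motif ``WRC`` with the CpG; or
* control — ``YCG`` or ``SNCG``, the CpG contexts that do *not* complete a
  ``WRC``; the two control patterns jointly tile all remaining NNCG prefixes.

Both strands are scanned (a minus-strand occurrence reads ``CGYW``/``CGNS``/
``CGR`` on the forward strand); an occurrence is identified by (contig,
genomic position of the C, orientation) and deduplicated across overlapping
windows.  The contrast asks whether target occurrences are hit at their
mutation-prone base (the C for plus-strand occurrences, the G for minus-
strand) more often than control occurrences — separating AID involvement
from generic CpG hypermutability — via a two-sided Fisher exact test on the
2x2 table [mutated/unmutated x target/control].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .enrichment import fisher_pvalue
from .io import MutationRecord, as_reference
from .motifs import IUPAC_CODES

_W = IUPAC_CODES["W"]
_R = IUPAC_CODES["R"]
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CpGOccurrence:
    """One classifiable CpG occurrence on one strand.

    ``pos`` is the 1-based genomic position of the C of the CpG;
    ``orientation`` is "+" (prefix upstream of the C) or "-" (read on the
    reverse strand; the mutation-prone base is then the G at ``pos``+1);
    ``is_target`` marks the WRCG class.
    """

    chrom: str
    pos: int
    orientation: str
    is_target: bool

    @property
    def mutable_pos(self) -> int:
        """1-based genomic position of the mutation-prone base."""
        return self.pos if self.orientation == "+" else self.pos + 1


@dataclass
class ContrastResult:
    """Fractions of mutated target (WRCG) vs control (YCG + SNCG) occurrences."""

    mutated_target: int
    total_target: int
    mutated_control: int
    total_control: int
    fisher_p: Optional[float] = None

    @property
    def computable(self) -> bool:
        return self.total_target > 0 and self.total_control > 0

    @property
    def fraction_target(self) -> float:
        return self.mutated_target / self.total_target if self.total_target else float("nan")

    @property
    def fraction_control(self) -> float:
        return (
            self.mutated_control / self.total_control if self.total_control else float("nan")
        )


def classify_prefix(b1: str, b2: str) -> Optional[bool]:
    """Classify the two bases immediately 5' of a CG (b1 b2 C G).

    Returns True for the WRCG class (b1 in W, b2 in R), False for the
    control class (everything else with defined bases — the YCG/SNCG union),
    None when a base is undefined.
    """
    if b1 not in _ACGT or b2 not in _ACGT:
        return None
    return b1 in _W and b2 in _R


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _classify_cg(seq_get, pos0: int) -> List[Tuple[int, str, bool]]:
    """Classify both orientations of the CG whose C is at 0-based ``pos0``.

    ``seq_get(i)`` returns the base at 0-based genomic offset ``i`` or None
    outside scope.  Yields (pos0, orientation, is_target) entries.
    """
    out: List[Tuple[int, str, bool]] = []
    # plus strand: b1 b2 C G with b1 at pos0-2
    b1, b2 = seq_get(pos0 - 2), seq_get(pos0 - 1)
    if b1 is not None and b2 is not None:
        cls = classify_prefix(b1, b2)
        if cls is not None:
            out.append((pos0, "+", cls))
    # minus strand: the reverse-complement occurrence's prefix lies 3' of the
    # G: C G b2' b1' on the forward strand, complemented and reversed.
    d1, d2 = seq_get(pos0 + 3), seq_get(pos0 + 2)
    if d1 is not None and d2 is not None and d1 in _ACGT and d2 in _ACGT:
        cls = classify_prefix(_COMP[d1], _COMP[d2])
        if cls is not None:
            out.append((pos0, "-", cls))
    return out


def enumerate_cpg_occurrences_in_windows(
    mutations: Sequence[MutationRecord],
) -> List[CpGOccurrence]:
    """Classified CpG occurrences over the union of mutation neighborhoods.

    Overlapping windows are merged by genomic coordinate, so duplicating a
    window cannot change the occurrence set.  CGs at window edges lacking the
    two prefix bases are excluded from both classes.
    """
    base_map: Dict[str, Dict[int, str]] = {}
    for rec in mutations:
        if rec.neighborhood is None or rec.center_index is None:
            raise ValueError(f"mutation {rec.chrom}:{rec.pos} has no neighborhood attached")
        chrom_map = base_map.setdefault(rec.chrom, {})
        start0 = rec.pos - 1 - rec.center_index
        for j, base in enumerate(rec.neighborhood):
            chrom_map[start0 + j] = base
    occurrences: List[CpGOccurrence] = []
    for chrom, cmap in base_map.items():
        get = cmap.get
        for pos0, base in cmap.items():
            if base == "C" and get(pos0 + 1) == "G":
                for p0, orient, is_t in _classify_cg(get, pos0):
                    occurrences.append(CpGOccurrence(chrom, p0 + 1, orient, is_t))
    occurrences.sort(key=lambda o: (o.chrom, o.pos, o.orientation))
    return occurrences


def enumerate_cpg_occurrences_in_regions(
    reference, regions: Iterable[Tuple[str, int, int]]
) -> List[CpGOccurrence]:
    """Classified CpG occurrences over explicit half-open (chrom, start0, end0) regions."""
    ref = as_reference(reference)
    seen: Set[Tuple[str, int, str]] = set()
    occurrences: List[CpGOccurrence] = []
    for chrom, start0, end0 in regions:
        pad_start = max(0, start0 - 2)
        pad_end = min(ref.length(chrom), end0 + 3)
        seq = ref.fetch(chrom, pad_start, pad_end)

        def get(i: int, _off=pad_start, _seq=seq):
            j = i - _off
            return _seq[j] if 0 <= j < len(_seq) else None

        for pos0 in range(start0, min(end0, ref.length(chrom) - 1)):
            if get(pos0) == "C" and get(pos0 + 1) == "G":
                for p0, orient, is_t in _classify_cg(get, pos0):
                    key = (chrom, p0, orient)
                    if key not in seen:
                        seen.add(key)
                        occurrences.append(CpGOccurrence(chrom, p0 + 1, orient, is_t))
    occurrences.sort(key=lambda o: (o.chrom, o.pos, o.orientation))
    return occurrences


def contrast_test(
    occurrences: Sequence[CpGOccurrence], mutations: Sequence[MutationRecord]
) -> ContrastResult:
    """Fisher contrast of mutated-fraction, target vs control occurrences.

    An occurrence is *mutated* when at least one dataset mutation coincides
    with its mutation-prone base — binary, since the contrast counts mutated
    motifs rather than mutations.
    """
    mutated_positions: Set[Tuple[str, int]] = {(m.chrom, m.pos) for m in mutations}
    mt = tt = mc = tc = 0
    for occ in occurrences:
        hit = (occ.chrom, occ.mutable_pos) in mutated_positions
        if occ.is_target:
            tt += 1
            mt += int(hit)
        else:
            tc += 1
            mc += int(hit)
    result = ContrastResult(
        mutated_target=mt, total_target=tt, mutated_control=mc, total_control=tc
    )
    if result.computable:
        result.fisher_p = fisher_pvalue(mt, tt, mc, tc)
    return result


def contrast_on_neighborhoods(
    mutations: Sequence[MutationRecord],
) -> ContrastResult:
    """End-to-end contrast over the union of mutation neighborhoods."""
    return contrast_test(enumerate_cpg_occurrences_in_windows(mutations), mutations)
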