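"""Degenerate IUPAC motifs with a designated mutation-prone base.

Deaminase target motifs (AID's WRC, APOBEC3's TCW, the hybrid WRCG, ...) are
short degenerate patterns in which one base is the mutation-prone one.  All
counting here is strand-symmetric: a genomic position "is a motif position"
when it aligns with the mutable base of an occurrence of the pattern on either
strand.  On the forward strand that means the pattern itself; on the reverse
strand it means the reverse complement of the pattern read on the forward
strand, with the mutable offset mirrored.  A position matching in both
orientations counts once.

Masked or undefined bases (``N``) match no code and are excluded from any
position totals by the callers.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Tuple

import numpy as np

#: IUPAC nucleotide codes -> set of concrete bases.  ``N`` in a *sequence*
#: never matches any code (handled by the matcher, not this table).
IUPAC_CODES: Dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Complement of each IUPAC code, defined set-wise (complement every member).
IUPAC_COMPLEMENT: Dict[str, str] = {}
for _code, _bases in IUPAC_CODES.items():
    _comp = frozenset(_COMPLEMENT_BASE[b] for b in _bases)
    for _c2, _b2 in IUPAC_CODES.items():
        if _b2 == _comp:
            IUPAC_COMPLEMENT[_code] = _c2
            break

_BASE_ORDER = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}

# membership lookup: code -> bool[5] over A,C,G,T,N (N matches nothing)
_CODE_LUT: Dict[str, np.ndarray] = {
    code: np.array([b in bases for b in "ACGT"] + [False])
    for code, bases in IUPAC_CODES.items()
}


def reverse_complement_sequence(seq: str) -> str:
    """Reverse complement of a concrete sequence over ``ACGTN``."""
    return "".join(_COMPLEMENT_BASE[b] for b in reversed(seq))


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (set-wise complement, reversed)."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def encode(seq: str) -> np.ndarray:
    """Encode a sequence over ``ACGTN`` as uint8 indices (A=0..N=4)."""
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid base {exc} in sequence") from exc


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC pattern with a designated mutation-prone position.

    Parameters
    ----------
    name:
        Short label such as ``"WRC"``.
    pattern:
        String over the IUPAC alphabet.
    mutable_index:
        0-based offset of the mutation-prone base within ``pattern``.  Must
        point at a concrete base or a two-fold degenerate code: a mutation has
        to be attributable to a specific prone base class, so ``N`` (or any
        3/4-fold code) is rejected there.
    """

    name: str
    pattern: str
    mutable_index: int

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad!r} in pattern {self.pattern!r}")
        if not 0 <= self.mutable_index < len(self.pattern):
            raise ValueError(
                f"mutable_index {self.mutable_index} out of range for {self.pattern!r}"
            )
        prone = self.pattern[self.mutable_index]
        if len(IUPAC_CODES[prone]) > 2:
            raise ValueError(
                f"mutable base {prone!r} is more than two-fold degenerate; the "
                "mutation-prone position must name a specific base class"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    def expand(self) -> FrozenSet[str]:
        """All concrete sequences matching the pattern.

        The size is the product of the degeneracies of the codes.
        """
        pools = [sorted(IUPAC_CODES[c]) for c in self.pattern]
        return frozenset("".join(p) for p in itertools.product(*pools))

    def reverse_complement(self) -> "DegenerateMotif":
        """Reverse complement motif with the mutable offset mirrored."""
        return DegenerateMotif(
            name=_revcomp_name(self.name, self.pattern),
            pattern=reverse_complement_pattern(self.pattern),
            mutable_index=len(self.pattern) - 1 - self.mutable_index,
        )

    def matches(self, word: str) -> bool:
        """Whether a concrete word of the motif's length fits the pattern."""
        if len(word) != len(self.pattern):
            return False
        return all(b in IUPAC_CODES[c] for b, c in zip(word, self.pattern))


def _revcomp_name(name: str, pattern: str) -> str:
    # The conventional label of a reverse complement is just the pattern's
    # reverse complement (WRC -> GYW); fall back to that when the name is the
    # pattern itself, otherwise tag it.
    if name == pattern:
        return reverse_complement_pattern(pattern)
    return name + "_rc"


@dataclass(frozen=True)
class MotifPair:
    """A motif together with its reverse complement, for double-stranded counting."""

    forward: DegenerateMotif
    reverse: DegenerateMotif

    def __post_init__(self) -> None:
        expected = self.forward.reverse_complement()
        if (
            self.reverse.pattern != expected.pattern
            or self.reverse.mutable_index != expected.mutable_index
        ):
            raise ValueError(
                f"reverse motif {self.reverse.pattern!r} is not the reverse "
                f"complement of {self.forward.pattern!r}"
            )

    @classmethod
    def from_forward(cls, motif: DegenerateMotif) -> "MotifPair":
        return cls(forward=motif, reverse=motif.reverse_complement())

    @property
    def name(self) -> str:
        return f"{self.forward.name}/{self.reverse.name}"

    @property
    def is_palindromic(self) -> bool:
        return self.forward.pattern == self.reverse.pattern


def _orientation_position_mask(codes: np.ndarray, motif: DegenerateMotif) -> np.ndarray:
    """Boolean array: position i aligns with the mutable base of an occurrence."""
    n = codes.shape[0]
    k = len(motif.pattern)
    out = np.zeros(n, dtype=bool)
    if n < k:
        return out
    starts = np.ones(n - k + 1, dtype=bool)
    for off, code in enumerate(motif.pattern):
        starts &= _CODE_LUT[code][codes[off : off + n - k + 1]]
    out[motif.mutable_index : motif.mutable_index + starts.shape[0]] = starts
    return out


def motif_position_mask(seq: str | np.ndarray, pair: MotifPair) -> np.ndarray:
    """Per-position booleans: is this position a motif position of ``pair``?

    True at position ``i`` when the base there sits at the mutable offset of a
    forward-strand occurrence or of a reverse-strand occurrence (the reverse
    complement pattern read on the forward strand).  Both orientations at one
    position count once — the result is boolean occupancy, so overlapping
    occurrences cannot double-count.
    """
    codes = seq if isinstance(seq, np.ndarray) else encode(seq)
    return _orientation_position_mask(codes, pair.forward) | _orientation_position_mask(
        codes, pair.reverse
    )


def matches_at(sequence: str, position: int, pair: MotifPair) -> bool:
    """Whether ``position`` of ``sequence`` is a motif position of ``pair``.

    ``N`` bases match nothing.  Out-of-range positions raise ``IndexError``.
    """
    if not 0 <= position < len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    for motif in (pair.forward, pair.reverse):
        k = len(motif.pattern)
        start = position - motif.mutable_index
        if start < 0 or start + k > len(sequence):
            continue
        if motif.matches(sequence[start : start + k]):
            return True
    return False


def scan_positions_bruteforce(sequence: str, pair: MotifPair) -> np.ndarray:
    """Independent oracle for :func:`motif_position_mask`.

    Slides every concrete expansion of both orientations over the sequence via
    regex lookahead and marks the mutable offset of each hit.  Slow; for tests.
    """
    out = np.zeros(len(sequence), dtype=bool)
    for motif in (pair.forward, pair.reverse):
        for word in motif.expand():
            for m in re.finditer(f"(?={re.escape(word)})", sequence):
                out[m.start() + motif.mutable_index] = True
    return out


def _pair(name: str, pattern: str, mutable_index: int) -> MotifPair:
    return MotifPair.from_forward(DegenerateMotif(name, pattern, mutable_index))


def default_catalog() -> Dict[str, MotifPair]:
    """The built-in motif set.

    Mutable positions: the deaminated C for all C-centred motifs; the A of WA
    (polymerase eta); for the CpG dinucleotide both bases count, which falls
    out of the strand pairing (forward CG marks the C, its reverse complement
    CG marks the G).
    """
    return {
        "CG": _pair("CG", "CG", 0),
        "TCW": _pair("TCW", "TCW", 1),
        "WRC": _pair("WRC", "WRC", 2),
        "WRCH": _pair("WRCH", "WRCH", 2),
        "WRCG": _pair("WRCG", "WRCG", 2),
        "WA": _pair("WA", "WA", 1),
        "YCG": _pair("YCG", "YCG", 1),
        "SNCG": _pair("SNCG", "SNCG", 2),
    }


def catalog_from_config(entries: Iterable[Tuple[str, str, int]]) -> Dict[str, MotifPair]:
    """Build a catalog from (name, pattern, mutable_index) triples."""
    out = {}
    for name, pattern, idx in entries:
        out[name] = _pair(name, pattern, int(idx))
    return out
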