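"""Readers and writers: mutations (TSV/VCF), reference FASTA, neighborhood
tables, methylation tables and result tables.

Coordinate conventions: every file interface is 1-based (VCF/TSV convention);
internally a record keeps its 1-based ``pos`` and, once a neighborhood is
attached, a 0-based ``center_index`` into that window.  Lower-case (soft
masked) reference bases are uppercased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: half-window size giving the canonical 121 nt neighborhood: 60 bases of
#: flank either side of the mutated base, i.e. 120 un-mutated local positions.
DEFAULT_FLANK = 60


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution, optionally with its neighborhood."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str = "sample"
    neighborhood: Optional[str] = None
    center_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single ACGT bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.neighborhood is not None:
            if self.center_index is None:
                raise ValueError("neighborhood without center_index")
            if not 0 <= self.center_index < len(self.neighborhood):
                raise ValueError("center_index outside neighborhood")
            if self.neighborhood[self.center_index] != self.ref:
                raise ValueError(
                    f"neighborhood center base {self.neighborhood[self.center_index]!r} "
                    f"does not equal ref {self.ref!r} at {self.chrom}:{self.pos}"
                )


@dataclass(frozen=True)
class MethylationSite:
    """A CpG position with bisulfite read counts and methylation ratio (0-100)."""

    chrom: str
    pos: int  # 1-based position of the CpG cytosine
    methylated_reads: int
    total_reads: int
    context: str = "unclassified"  # WRCG | control | other | unclassified
    mutated: bool = False

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"total_reads must be positive at {self.chrom}:{self.pos}")
        if not 0 <= self.methylated_reads <= self.total_reads:
            raise ValueError(
                f"methylated_reads out of range at {self.chrom}:{self.pos}: "
                f"{self.methylated_reads}/{self.total_reads}"
            )

    @property
    def ratio(self) -> float:
        """100 x methylated / total."""
        return 100.0 * self.methylated_reads / self.total_reads


@dataclass
class ReadReport:
    """Bookkeeping from a reader: how many records were skipped and why."""

    n_read: int = 0
    n_skipped_non_snv: int = 0
    messages: List[str] = field(default_factory=list)


def _clean_seq(seq: str) -> str:
    return seq.upper()


def read_mutations_tsv(path: str | Path, report: Optional[ReadReport] = None) -> List[MutationRecord]:
    """Read mutations from a whitespace/tab separated table.

    Columns: chrom, pos (1-based), ref, alt, sample_id (optional 5th).  Lines
    starting with ``#`` are comments.  Non-SNV rows (multi-base ref or alt)
    are skipped and counted; malformed rows raise with their line number.
    """
    report = report if report is not None else ReadReport()
    records: List[MutationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
            chrom, pos_s, ref, alt = parts[:4]
            sample = parts[4] if len(parts) > 4 else "sample"
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer")
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES or ref == alt:
                report.n_skipped_non_snv += 1
                continue
            records.append(MutationRecord(chrom, pos, ref, alt, sample))
            report.n_read += 1
    if report.n_skipped_non_snv:
        logger.info("skipped %d non-SNV records in %s", report.n_skipped_non_snv, path)
    return records


def read_mutations_vcf(path: str | Path, report: Optional[ReadReport] = None) -> List[MutationRecord]:
    """Read single-base substitutions from a VCF.

    Multi-allelic records yield one :class:`MutationRecord` per SNV allele;
    indel or symbolic alleles are skipped and counted.  The sample id is taken
    from the first VCF sample name when present, else the file stem.
    """
    from cyvcf2 import VCF

    report = report if report is not None else ReadReport()
    vcf = VCF(str(path))
    default_sample = vcf.samples[0] if vcf.samples else Path(path).stem
    records: List[MutationRecord] = []
    for variant in vcf:
        ref = variant.REF.upper()
        for alt in variant.ALT:
            alt = alt.upper()
            if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and ref != alt:
                records.append(
                    MutationRecord(variant.CHROM, variant.POS, ref, alt, default_sample)
                )
                report.n_read += 1
            else:
                report.n_skipped_non_snv += 1
    if report.n_skipped_non_snv:
        logger.info("skipped %d non-SNV alleles in %s", report.n_skipped_non_snv, path)
    return records


def read_mutations(
    path: str | Path, format: str = "tsv", report: Optional[ReadReport] = None
) -> List[MutationRecord]:
    """Dispatch on ``format`` in {"tsv", "vcf"}."""
    if format == "tsv":
        return read_mutations_tsv(path, report)
    if format == "vcf":
        return read_mutations_vcf(path, report)
    raise ValueError(f"unknown mutation format {format!r}")


class _DictReference:
    """Minimal FASTA-accessor interface over a {name: sequence} mapping."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {k: _clean_seq(v) for k, v in contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    def fetch(self, name: str, start0: int, end0: int) -> str:
        return self._contigs[name][start0:end0]


class FastaReference(_DictReference):
    """Reference accessor backed by pyfaidx (random access, .fai-indexed)."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, name: str) -> bool:
        return name in self._fasta

    def length(self, name: str) -> int:
        return len(self._fasta[name])

    def fetch(self, name: str, start0: int, end0: int) -> str:
        return str(self._fasta[name][start0:end0])


def as_reference(reference) -> _DictReference:
    """Accept a path to a FASTA, a mapping, or an accessor, uniformly."""
    if isinstance(reference, (str, Path)):
        return FastaReference(reference)
    if isinstance(reference, Mapping):
        return _DictReference(reference)
    return reference


def attach_neighborhoods(
    mutations: Sequence[MutationRecord],
    reference,
    flank: int = DEFAULT_FLANK,
) -> List[MutationRecord]:
    """Attach the local sequence window (``flank`` bases either side) to each record.

    Windows are truncated at contig ends with ``center_index`` adjusted.  A
    mismatch between the record's ref base and the reference sequence is an
    error listing the offending records; so is a locus absent from the
    reference.
    """
    ref = as_reference(reference)
    out: List[MutationRecord] = []
    mismatches: List[str] = []
    for rec in mutations:
        if rec.chrom not in ref:
            raise KeyError(f"contig {rec.chrom!r} absent from reference")
        clen = ref.length(rec.chrom)
        if not 1 <= rec.pos <= clen:
            raise IndexError(f"locus {rec.chrom}:{rec.pos} outside contig of length {clen}")
        center0 = rec.pos - 1
        start0 = max(0, center0 - flank)
        end0 = min(clen, center0 + flank + 1)
        window = _clean_seq(ref.fetch(rec.chrom, start0, end0))
        ci = center0 - start0
        if window[ci] != rec.ref:
            mismatches.append(f"{rec.chrom}:{rec.pos} ref={rec.ref} reference={window[ci]}")
            continue
        out.append(replace(rec, neighborhood=window, center_index=ci))
    if mismatches:
        shown = "; ".join(mismatches[:10])
        raise ValueError(
            f"{len(mismatches)} record(s) disagree with the reference: {shown}"
        )
    return out


def read_neighborhoods_tsv(path: str | Path) -> List[MutationRecord]:
    """Read pre-extracted neighborhoods.

    Columns: chrom, pos (1-based), ref, alt, sample_id, neighborhood,
    center_index (0-based).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "sample_id", "neighborhood", "center_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"neighborhood table missing columns {sorted(missing)}")
    return [
        MutationRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref).upper(),
            alt=str(r.alt).upper(),
            sample_id=str(r.sample_id),
            neighborhood=_clean_seq(str(r.neighborhood)),
            center_index=int(r.center_index),
        )
        for r in df.itertuples(index=False)
    ]


def write_neighborhoods_tsv(mutations: Sequence[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "sample_id": [m.sample_id for m in mutations],
            "neighborhood": [m.neighborhood for m in mutations],
            "center_index": [m.center_index for m in mutations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_mutations_tsv(mutations: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tsample_id\n")
        for m in mutations:
            fh.write(f"{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.sample_id}\n")


def write_vcf(mutations: Sequence[MutationRecord], path: str | Path) -> None:
    """Write a minimal sites-only VCF 4.2 of the substitutions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in mutations:
            fh.write(f"{m.chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t.\tPASS\tSAMPLE={m.sample_id}\n")


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_methylation(path: str | Path) -> List[MethylationSite]:
    """Read per-CpG methylation counts.

    Columns: chrom, pos (1-based C of the CpG), methylated reads, total reads.
    The ratio is derived from the counts; no depth filtering happens here.
    """
    sites: List[MethylationSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, pos_s, meth_s, tot_s = parts[:4]
            sites.append(
                MethylationSite(
                    chrom=chrom,
                    pos=int(pos_s),
                    methylated_reads=int(meth_s),
                    total_reads=int(tot_s),
                )
            )
    return sites


def write_methylation(sites: Sequence[MethylationSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tmethylated_reads\ttotal_reads\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.methylated_reads}\t{s.total_reads}\n")


RESULT_COLUMNS = [
    "motif",
    "n_mutations",
    "n_in_motif",
    "Fm",
    "Fn",
    "excess",
    "fisher_p",
    "mc_p",
    "bonferroni_flag",
]


def write_results(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Write enrichment results as a TSV mirroring the study's summary tables.

    ``results`` are objects exposing the fields of ``RESULT_COLUMNS`` (see
    :class:`aidsig.enrichment.EnrichmentResult`).  Rows keep input order;
    the frame written is returned for convenience.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "motif": r.motif_name,
                "n_mutations": r.n_mutations,
                "n_in_motif": r.k_in_motif,
                "Fm": r.fm,
                "Fn": r.fn,
                "excess": r.excess,
                "fisher_p": r.fisher_p,
                "mc_p": r.mc_p,
                "bonferroni_flag": bool(getattr(r, "bonferroni_significant", False)),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed_regions(path: str | Path) -> List[Tuple[str, int, int]]:
    """Read BED3 regions as (chrom, start0, end0) half-open intervals."""
    regions: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


def restrict_to_regions(
    mutations: Sequence[MutationRecord], regions: Sequence[Tuple[str, int, int]]
) -> List[MutationRecord]:
    """Keep mutations whose (1-based) position falls in any half-open region."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for m in mutations:
        p0 = m.pos - 1
        if any(s <= p0 < e for s, e in by_chrom.get(m.chrom, ())):
            out.append(m)
    return out
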