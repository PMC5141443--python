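"""Published cohort summary statistics and external validation targets.

``COSMIC_WRC_COHORTS`` holds per-tissue summaries from published analyses of
the Sanger COSMIC Whole Genome Project (v75) cohorts: the fraction of somatic
mutations falling at the mutable position of the AID motif WRC/GYW (``fm``,
with the number of mutations in brackets in the source tables) and the
frequency of WRC/GYW positions among un-mutated neighborhood bases (``fn``).
The excess statistic Fm/Fn is *recomputed* from these fractions by
:func:`cohort_excess`; the published, rounded excess values are kept solely
for cross-checking.

``EXTERNAL_TARGETS`` registers quantities that can only be validated against
the full external datasets (follicular-lymphoma exome calls plus a human
reference genome, COSMIC v75 downloads, ICGC project MALY-DE).  Each entry
names the datasets it needs and the callable that computes it once those are
supplied; :func:`evaluate_external_targets` runs whichever targets have their
inputs and marks the rest unavailable.  Nothing here downloads anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence

from .enrichment import excess_from_fractions


@dataclass(frozen=True)
class CohortSummary:
    """One tissue cohort's published WRC/GYW summary fractions."""

    tissue: str
    fm: float  # fraction of mutations at the motif's mutable position
    n_mutations: int
    fn: float  # motif frequency among un-mutated neighborhood positions
    n_positions: int
    published_excess: float  # rounded value printed in the source table


COSMIC_WRC_COHORTS: Dict[str, CohortSummary] = {
    s.tissue: s
    for s in (
        CohortSummary("Blood", 0.265, 10_633, 0.222, 630_338, 1.19),
        CohortSummary("Blood: Acute Myeloid Leukemia", 0.254, 6_844, 0.221, 405_754, 1.15),
        CohortSummary("Blood: GCB Lymphomas", 0.296, 2_747, 0.221, 165_805, 1.34),
        CohortSummary("Breast", 0.146, 85_203, 0.230, 4_877_914, 0.64),
        CohortSummary("Bladder", 0.093, 38_750, 0.229, 2_247_271, 0.41),
        CohortSummary("Cervix", 0.074, 41_454, 0.229, 2_399_601, 0.32),
        CohortSummary("Colon", 0.257, 175_109, 0.221, 8_986_392, 1.16),
        CohortSummary("Kidney", 0.225, 32_382, 0.228, 1_875_298, 0.99),
        CohortSummary("Liver", 0.226, 74_161, 0.222, 4_426_455, 1.02),
        CohortSummary("Lung", 0.174, 180_284, 0.226, 9_867_123, 0.77),
        CohortSummary("Ovary", 0.229, 22_340, 0.225, 1_309_849, 1.02),
        CohortSummary("Pancreas", 0.227, 35_165, 0.220, 2_112_760, 1.03),
        CohortSummary("Prostate", 0.22, 13_036, 0.222, 775_226, 0.99),
        CohortSummary("Rectum", 0.223, 23_330, 0.226, 1_343_391, 0.99),
        CohortSummary("Skin", 0.050, 198_098, 0.224, 8_986_960, 0.22),
        CohortSummary("Stomach", 0.274, 115_652, 0.221, 6_977_875, 1.24),
        CohortSummary("Uterus", 0.254, 55_999, 0.229, 3_212_849, 1.11),
    )
}


def cohort_excess(tissue: str) -> float:
    """Recompute the excess Fm/Fn for a published cohort from its fractions."""
    s = COSMIC_WRC_COHORTS[tissue]
    return excess_from_fractions(s.fm, s.fn)


def cohort_effect_size(tissue: str) -> float:
    """Fm - Fn for a published cohort (the power-analysis effect size)."""
    s = COSMIC_WRC_COHORTS[tissue]
    return s.fm - s.fn


@dataclass(frozen=True)
class ExternalTarget:
    """A quantity checkable only against an external dataset."""

    name: str
    expected: float
    description: str
    required_datasets: Sequence[str]
    compute: Optional[Callable[[Mapping[str, str]], float]] = None


def _fl_wrcg_excess(paths: Mapping[str, str]) -> float:
    from .enrichment import compute_enrichment
    from .io import attach_neighborhoods, read_mutations
    from .motifs import default_catalog

    muts = read_mutations(paths["fl_mutations"], format="tsv")
    muts = attach_neighborhoods(muts, paths["reference_fasta"])
    res = compute_enrichment(muts, default_catalog()["WRCG"], mc_reps=0)
    return float(res.excess)


def _fl_cg_excess(paths: Mapping[str, str]) -> float:
    from .enrichment import compute_enrichment
    from .io import attach_neighborhoods, read_mutations
    from .motifs import default_catalog

    muts = read_mutations(paths["fl_mutations"], format="tsv")
    muts = attach_neighborhoods(muts, paths["reference_fasta"])
    res = compute_enrichment(muts, default_catalog()["CG"], mc_reps=0)
    return float(res.excess)


def _maly_excess(motif: str) -> Callable[[Mapping[str, str]], float]:
    def compute(paths: Mapping[str, str]) -> float:
        from .enrichment import compute_enrichment
        from .io import attach_neighborhoods, read_mutations
        from .motifs import default_catalog

        muts = read_mutations(paths["maly_mutations"], format="tsv")
        muts = attach_neighborhoods(muts, paths["reference_fasta"])
        res = compute_enrichment(muts, default_catalog()[motif], mc_reps=0)
        return float(res.excess)

    return compute


def _maly_methylation_mean(context: str) -> Callable[[Mapping[str, str]], float]:
    def compute(paths: Mapping[str, str]) -> float:
        from .io import attach_neighborhoods, read_methylation, read_mutations
        from .methylation import classify_context, filter_by_depth

        sites = filter_by_depth(read_methylation(paths["maly_methylation"]))
        muts = read_mutations(paths["maly_mutations"], format="tsv")
        sites = classify_context(sites, paths["reference_fasta"], muts)
        ratios = [s.ratio for s in sites if s.mutated and s.context == context]
        if not ratios:
            raise ValueError("no sites in group")
        return float(sum(ratios) / len(ratios))

    return compute


EXTERNAL_TARGETS: Dict[str, ExternalTarget] = {
    t.name: t
    for t in (
        ExternalTarget(
            "fl_exome_wrcg_excess",
            2.7,
            "WRCG/CGYW excess in pooled follicular-lymphoma exomes",
            ("fl_mutations", "reference_fasta"),
            _fl_wrcg_excess,
        ),
        ExternalTarget(
            "fl_exome_cg_excess",
            2.3,
            "CG/CG excess in pooled follicular-lymphoma exomes",
            ("fl_mutations", "reference_fasta"),
            _fl_cg_excess,
        ),
        ExternalTarget(
            "maly_wrcg_excess",
            4.91,
            "WRCG/CGYW excess in the ICGC MALY-DE lymphoma cohort",
            ("maly_mutations", "reference_fasta"),
            _maly_excess("WRCG"),
        ),
        ExternalTarget(
            "maly_wrc_excess",
            1.53,
            "WRC/GYW excess in the ICGC MALY-DE lymphoma cohort",
            ("maly_mutations", "reference_fasta"),
            _maly_excess("WRC"),
        ),
        ExternalTarget(
            "maly_methylation_mean_wrcg",
            74.8,
            "mean methylation ratio at mutated WRCG-context CpGs (MALY-DE)",
            ("maly_methylation", "maly_mutations", "reference_fasta"),
            _maly_methylation_mean("WRCG"),
        ),
        ExternalTarget(
            "maly_methylation_mean_control",
            79.4,
            "mean methylation ratio at mutated control-context CpGs (MALY-DE)",
            ("maly_methylation", "maly_mutations", "reference_fasta"),
            _maly_methylation_mean("control"),
        ),
    )
}


def evaluate_external_targets(
    data_paths: Optional[Mapping[str, str]] = None,
) -> Dict[str, dict]:
    """Compute every external target whose datasets are supplied.

    Returns per target a dict with ``expected``, ``status`` ("computed" or
    "unavailable"), ``value`` (when computed) and the datasets still missing.
    """
    data_paths = dict(data_paths or {})
    out: Dict[str, dict] = {}
    for name, target in EXTERNAL_TARGETS.items():
        missing = [d for d in target.required_datasets if d not in data_paths]
        entry = {"expected": target.expected, "description": target.description}
        if missing or target.compute is None:
            entry["status"] = "unavailable"
            entry["missing_datasets"] = missing
        else:
            entry["status"] = "computed"
            entry["value"] = target.compute(data_paths)
        out[name] = entry
    return out
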