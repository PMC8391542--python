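"""The CNV filter cascade: Bayes-factor, size, population-frequency and
recurrence filters, plus distinct-call deduplication.

All filters are pure predicates over call lists: survivors are always a
subset of the input, each filter is idempotent, and the BF/size/AF filters
commute.  Only stated exclusion conditions are applied, so boundary values
(BF exactly 1, size exactly 100 bp, frequency exactly 0.01) are kept.

Population-frequency filtering is gene-based: overlapping CNVs have no crisp
boundaries, so each gene takes the maximum heterozygous-loss frequency over
all eligible database records (records from surveys of fewer than 100 samples
are ignored), and a gene above the frequency cutoff is excluded together with
its calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .depth_caller import CnvCall, call_genes, gene_exon_annotation
from .synthetic_cohort import ExonTarget, PedigreeRecord, PopFreqRecord

__all__ = [
    "FilterThresholds",
    "GeneCnvGroup",
    "filter_by_bf",
    "filter_by_size",
    "annotate_genes",
    "eligible_max_af",
    "gene_max_af",
    "count_distinct",
    "count_recurrence",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs of the filter cascade (defaults are the study settings)."""

    min_bf: float = 1.0
    min_size_bp: int = 100
    max_pop_af: float = 0.01
    min_db_sample_size: int = 100
    max_control_fraction: float = 0.01
    min_patient_count: int = 4

    def __post_init__(self) -> None:
        if min(self.min_size_bp, self.min_db_sample_size, self.min_patient_count) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.max_pop_af <= 1 and 0 <= self.max_control_fraction <= 1):
            raise ValueError("fraction thresholds must lie in [0,1]")


@dataclass
class GeneCnvGroup:
    """All calls touching one gene, with carrier counts and population frequency."""

    gene: str
    calls: list[CnvCall] = field(default_factory=list)
    patient_count: int = 0
    control_count: int = 0
    max_pop_af: Optional[float] = None


def filter_by_bf(calls: Sequence[CnvCall], thresholds: FilterThresholds) -> list[CnvCall]:
    """Keep calls whose Bayes factor is at least ``min_bf``."""
    return [c for c in calls if c.bayes_factor >= thresholds.min_bf]


def filter_by_size(calls: Sequence[CnvCall], thresholds: FilterThresholds) -> list[CnvCall]:
    """Keep calls spanning at least ``min_size_bp`` base pairs."""
    return [c for c in calls if c.size >= thresholds.min_size_bp]


def annotate_genes(
    calls: Sequence[CnvCall], targets: Sequence[ExonTarget]
) -> list[CnvCall]:
    """Assign each call its overlapped genes/exons as "GENE_a-b" annotation.

    Calls overlapping no target keep an empty annotation; they are retained
    but invisible to every gene-based stage.
    """
    return [
        replace(
            c,
            exon_annotation=gene_exon_annotation(c.chrom, c.start, c.end, targets),
        )
        for c in calls
    ]


def eligible_max_af(
    gene: str, popfreq: Sequence[PopFreqRecord], thresholds: FilterThresholds
) -> Optional[float]:
    """Maximum heterozygous-loss frequency over eligible records for a gene.

    A record is eligible when its survey sample size reaches
    ``min_db_sample_size``; the East-Asian frequency participates whenever
    present.  Returns None when the gene has no eligible record.
    """
    values: list[float] = []
    for rec in popfreq:
        if rec.gene != gene or rec.sample_size < thresholds.min_db_sample_size:
            continue
        values.append(rec.freq_het_loss)
        if rec.freq_het_loss_east_asia is not None:
            values.append(rec.freq_het_loss_east_asia)
    return max(values) if values else None


def gene_max_af(
    calls: Sequence[CnvCall],
    popfreq: Sequence[PopFreqRecord],
    thresholds: FilterThresholds,
) -> tuple[dict[str, GeneCnvGroup], list[CnvCall]]:
    """Gene-based population-frequency filter.

    Returns the per-gene groups (with ``max_pop_af`` filled in) for the genes
    that survive, and the filtered call list.  A gene is excluded when its
    maximum eligible frequency exceeds ``max_pop_af``; genes with no eligible
    record are retained.  A call survives when at least one of its annotated
    genes survives; unannotated calls pass through untouched.
    """
    groups: dict[str, GeneCnvGroup] = {}
    for call in calls:
        for gene in call_genes(call):
            groups.setdefault(gene, GeneCnvGroup(gene)).calls.append(call)
    surviving: dict[str, GeneCnvGroup] = {}
    for gene, group in groups.items():
        group.max_pop_af = eligible_max_af(gene, popfreq, thresholds)
        if group.max_pop_af is None or group.max_pop_af <= thresholds.max_pop_af:
            surviving[gene] = group
    kept: list[CnvCall] = []
    for call in calls:
        genes = call_genes(call)
        if not genes or any(g in surviving for g in genes):
            kept.append(call)
    return surviving, kept


def count_distinct(calls: Sequence[CnvCall]) -> int:
    """Number of distinct CNVs: equivalence classes of (chrom, start, end, type)."""
    return len({(c.chrom, c.start, c.end, c.type) for c in calls})


def count_recurrence(
    calls: Sequence[CnvCall], pedigrees: Sequence[PedigreeRecord]
) -> dict[str, GeneCnvGroup]:
    """Per gene, count distinct affected and unaffected carriers.

    A sample carries a gene when it has at least one call overlapping it.
    Every call's sample must be present in the pedigree.
    """
    affected = {p.sample_id: p.affected for p in pedigrees}
    groups: dict[str, GeneCnvGroup] = {}
    carriers: dict[str, set[str]] = {}
    for call in calls:
        if call.sample_id not in affected:
            raise KeyError(f"sample {call.sample_id} absent from pedigree")
        for gene in call_genes(call):
            groups.setdefault(gene, GeneCnvGroup(gene)).calls.append(call)
            carriers.setdefault(gene, set()).add(call.sample_id)
    for gene, group in groups.items():
        group.patient_count = sum(1 for s in carriers[gene] if affected[s])
        group.control_count = sum(1 for s in carriers[gene] if not affected[s])
    return groups
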