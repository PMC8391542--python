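"""The three result surfaces of the analysis, plus qPCR validation arithmetic.

1. Candidate-gene screen: rare CNVs overlapping genes known for scoliosis or
   somitogenesis, with per-family inheritance patterns.
2. Recessive screen: homozygous CNVs (observed/expected ratio < 0.1) unique
   to patients, i.e. never homozygous in any control.
3. Novel enrichment: genes recurrently hit in more than three patients but
   absent or very rare (< 1%) among family controls and rare (<= 1%) in the
   population databases; discovery is run on patients from complete families
   (both parents assayed) and the counts are then updated with the remaining
   patients.

The ΔΔCt calculator turns qPCR cycle thresholds into relative quantities
(2^-ΔΔCt) and autosomal copy-number estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cnv_filters import FilterThresholds, GeneCnvGroup, eligible_max_af
from .depth_caller import CnvCall, call_genes
from .family_genetics import (
    InheritanceCall,
    classify_inheritance,
    detect_recessive,
    patient_unique_homozygous,
)
from .synthetic_cohort import PedigreeRecord, PopFreqRecord

__all__ = [
    "DEFAULT_CANDIDATE_GENES",
    "QpcrMeasurement",
    "complete_family_split",
    "candidate_gene_screen",
    "recessive_screen",
    "novel_enrichment",
    "qpcr_relative_quantity",
]

#: scoliosis- and somitogenesis-associated genes used by the candidate screen
DEFAULT_CANDIDATE_GENES = frozenset(
    {
        "TBX6",
        "NOTCH2",
        "DSCAM",
        "SNTG1",
        "DLL3",
        "MESP2",
        "LFNG",
        "HES7",
        "RIPPLY2",
        "TBXT",
        "SOX9",
    }
)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Triplicate-averaged qPCR cycle thresholds for one sample and locus."""

    sample_id: str
    target_locus: str
    reference_locus: str
    ct_target: float
    ct_reference: float
    calibrator_id: str

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


def _call_key(call: CnvCall) -> tuple:
    return (call.sample_id, call.chrom, call.start, call.end, call.type)


def _freq_columns(
    gene: str, popfreq: Sequence[PopFreqRecord], thresholds: FilterThresholds
) -> dict[str, Optional[float]]:
    """Per-database eligible frequencies for report rows."""
    dgv = [
        r.freq_het_loss
        for r in popfreq
        if r.gene == gene
        and r.database == "DGV-like"
        and r.sample_size >= thresholds.min_db_sample_size
    ]
    gnomad = [
        r
        for r in popfreq
        if r.gene == gene
        and r.database == "gnomAD-like"
        and r.sample_size >= thresholds.min_db_sample_size
    ]
    east = [r.freq_het_loss_east_asia for r in gnomad if r.freq_het_loss_east_asia is not None]
    return {
        "freq_dgv": max(dgv) if dgv else None,
        "freq_gnomad": max(r.freq_het_loss for r in gnomad) if gnomad else None,
        "freq_gnomad_east_asia": max(east) if east else None,
    }


def complete_family_split(
    pedigrees: Sequence[PedigreeRecord],
) -> tuple[set[str], set[str]]:
    """Patients from complete families (both parents assayed) vs the rest."""
    ids = {p.sample_id for p in pedigrees}
    complete: set[str] = set()
    other: set[str] = set()
    for p in pedigrees:
        if not p.affected:
            continue
        if p.father_id in ids and p.mother_id in ids:
            complete.add(p.sample_id)
        else:
            other.add(p.sample_id)
    return complete, other


# ---------------------------------------------------------------------------
# Candidate-gene screen
# ---------------------------------------------------------------------------

def candidate_gene_screen(
    filtered_calls: Sequence[CnvCall],
    candidates: Iterable[str],
    inheritance: Sequence[InheritanceCall],
    popfreq: Sequence[PopFreqRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Report rows for patient calls overlapping candidate genes.

    Input calls are expected to be BF- and frequency-filtered already; the
    size filter is deliberately not applied on this path so short single-exon
    candidate hits survive.  One row per (call, overlapped candidate gene),
    sorted by gene then sample.
    """
    candidate_set = set(candidates)
    pattern_by_key = {_call_key(ic.patient_call): ic for ic in inheritance}
    rows = []
    for call in filtered_calls:
        for gene in dict.fromkeys(call_genes(call)):
            if gene not in candidate_set:
                continue
            ic = pattern_by_key.get(_call_key(call))
            rows.append(
                {
                    "gene": gene,
                    "sample_id": call.sample_id,
                    "type": call.type,
                    "chrom": call.chrom,
                    "start": call.start,
                    "end": call.end,
                    "size_bp": call.size,
                    "bayes_factor": call.bayes_factor,
                    "reads_ratio": call.reads_ratio,
                    "exon_annotation": call.exon_annotation,
                    "inheritance": ic.label if ic else "N.D.",
                    **_freq_columns(gene, popfreq, thresholds),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "sample_id", "type", "chrom", "start", "end", "size_bp",
            "bayes_factor", "reads_ratio", "exon_annotation", "inheritance",
            "freq_dgv", "freq_gnomad", "freq_gnomad_east_asia",
        ],
    )
    return frame.sort_values(["gene", "sample_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Recessive screen
# ---------------------------------------------------------------------------

def recessive_screen(
    patient_calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    pedigrees: Sequence[PedigreeRecord],
    popfreq: Sequence[PopFreqRecord] = (),
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Patient-unique homozygous CNVs with inheritance annotation.

    Composition: detect homozygous calls (ratio < 0.1) in patients and
    controls, drop patient genes that are also homozygous in a control, then
    classify each surviving call against the family.  Rows grouped by gene.
    """
    hom_patients = detect_recessive(patient_calls)
    hom_controls = detect_recessive(control_calls)
    unique = patient_unique_homozygous(hom_patients, hom_controls)
    all_calls = list(patient_calls) + list(control_calls)
    rows = []
    for call in unique:
        ic = classify_inheritance(call, all_calls, pedigrees)
        genes = list(dict.fromkeys(call_genes(call)))
        gene = genes[0] if genes else ""
        label = ic.label
        if ic.sibling_checked and ic.sibling_absent and ic.pattern == "de_novo":
            label = "* " + label  # also absent from assayed healthy siblings
        rows.append(
            {
                "gene": gene,
                "sample_id": call.sample_id,
                "type": call.type,
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "size_bp": call.size,
                "bayes_factor": call.bayes_factor,
                "reads_ratio": call.reads_ratio,
                "exon_annotation": call.exon_annotation,
                "inheritance": label,
                **_freq_columns(gene, popfreq, thresholds),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "sample_id", "type", "chrom", "start", "end", "size_bp",
            "bayes_factor", "reads_ratio", "exon_annotation", "inheritance",
            "freq_dgv", "freq_gnomad", "freq_gnomad_east_asia",
        ],
    )
    return frame.sort_values(["gene", "sample_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Novel enrichment
# ---------------------------------------------------------------------------

def novel_enrichment(
    gene_groups: Mapping[str, GeneCnvGroup],
    thresholds: FilterThresholds,
    complete_family_patients: set[str],
    other_patients: set[str],
    n_controls: int,
    popfreq: Sequence[PopFreqRecord] = (),
) -> pd.DataFrame:
    """Genes recurrently hit in patients but rare in controls and populations.

    Two passes: a gene enters discovery only if at least one of its patient
    carriers comes from a complete family; carrier counts then include the
    remaining patients.  A gene is reported when its patient count is at
    least ``min_patient_count`` (the "more than three patients" rule), its
    control carrier fraction is below ``max_control_fraction``, and its
    maximum eligible population frequency does not exceed ``max_pop_af``.
    """
    rows = []
    for gene in sorted(gene_groups):
        group = gene_groups[gene]
        carriers = {c.sample_id for c in group.calls}
        if not (carriers & complete_family_patients):
            continue  # never discovered in the complete-family pass
        patient_count = len(carriers & (complete_family_patients | other_patients))
        control_count = group.control_count
        if patient_count < thresholds.min_patient_count:
            continue
        if n_controls > 0:
            if control_count / n_controls >= thresholds.max_control_fraction:
                continue
        elif control_count > 0:
            continue
        max_af = group.max_pop_af
        if max_af is None:
            max_af = eligible_max_af(gene, popfreq, thresholds)
        if max_af is not None and max_af > thresholds.max_pop_af:
            continue
        sizes = sorted(c.size for c in group.calls)
        types = sorted({c.type for c in group.calls})
        chroms = sorted({c.chrom for c in group.calls})
        rows.append(
            {
                "gene": gene,
                "type": "/".join(types),
                "chrom": "/".join(chroms),
                "size_range_bp": (
                    f"{sizes[0]}" if sizes[0] == sizes[-1] else f"{sizes[0]}-{sizes[-1]}"
                ),
                "patient_count": patient_count,
                "control_count": control_count,
                **_freq_columns(gene, popfreq, thresholds),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "type", "chrom", "size_range_bp", "patient_count",
            "control_count", "freq_dgv", "freq_gnomad", "freq_gnomad_east_asia",
        ],
    )


# ---------------------------------------------------------------------------
# qPCR validation
# ---------------------------------------------------------------------------

def qpcr_relative_quantity(measurements: Sequence[QpcrMeasurement]) -> pd.DataFrame:
    """Relative locus quantity by the 2^-ΔΔCt method.

    ΔCt = Ct(target) - Ct(reference locus); ΔΔCt subtracts the calibrator
    sample's ΔCt for the same target locus; relative quantity is 2^-ΔΔCt and
    the autosomal copy estimate doubles it (calibrator assumed diploid).
    """
    if not measurements:
        raise ValueError("no measurements given")
    dct_by_sample: dict[tuple[str, str], float] = {}
    for m in measurements:
        dct_by_sample[(m.target_locus, m.sample_id)] = m.ct_target - m.ct_reference
    rows = []
    for m in measurements:
        key = (m.target_locus, m.calibrator_id)
        if key not in dct_by_sample:
            raise ValueError(
                f"calibrator {m.calibrator_id!r} has no measurement for locus "
                f"{m.target_locus!r}"
            )
        dct = dct_by_sample[(m.target_locus, m.sample_id)]
        ddct = dct - dct_by_sample[key]
        rq = 2.0 ** (-ddct)
        rows.append(
            {
                "sample_id": m.sample_id,
                "target_locus": m.target_locus,
                "delta_ct": dct,
                "delta_delta_ct": ddct,
                "relative_quantity": rq,
                "copy_estimate": 2.0 * rq,
            }
        )
    return pd.DataFrame(rows)
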