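"""Inheritance classification against available relatives and detection of
patient-unique recessive (homozygous) CNVs.

Parental carriage is judged on each parent's own call set, mirroring a
per-sample read-depth workflow: a parent carries the variant when it has a
call of the same type that either shares an annotated gene (default) or
reciprocally overlaps the patient call by at least 50% (interval mode).
Inherited calls from independent per-sample calling often differ in exact
boundaries, which is why gene-level matching is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .depth_caller import CnvCall, HOM_RATIO_THRESHOLD, call_genes
from .synthetic_cohort import PedigreeRecord

__all__ = [
    "InheritanceCall",
    "PATTERN_LABELS",
    "classify_inheritance",
    "detect_recessive",
    "patient_unique_homozygous",
]

#: report-facing labels for each inheritance pattern
PATTERN_LABELS = {
    "de_novo": "De novo",
    "paternal": "Paternal",
    "maternal": "Maternal",
    "biparental": "Biparental",
    "not_determined": "N.D.",
}


@dataclass(frozen=True)
class InheritanceCall:
    """Inheritance verdict for one patient call.

    ``sibling_checked``/``sibling_absent`` are informative annotations set
    only when at least one unaffected sibling was assayed; sibling absence is
    never required for the de novo label.
    """

    patient_call: CnvCall
    pattern: str  # key of PATTERN_LABELS
    sibling_checked: bool = False
    sibling_absent: bool = False

    @property
    def label(self) -> str:
        return PATTERN_LABELS[self.pattern]


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.size, inter / b.size)


def _carries(
    carrier_calls: Iterable[CnvCall], patient_call: CnvCall, overlap_rule: str
) -> bool:
    patient_genes = set(call_genes(patient_call))
    for call in carrier_calls:
        if call.type != patient_call.type:
            continue
        if overlap_rule == "gene":
            if patient_genes and patient_genes & set(call_genes(call)):
                return True
        elif overlap_rule == "interval":
            if _reciprocal_overlap(patient_call, call) >= 0.5:
                return True
        else:
            raise ValueError(f"unknown overlap_rule: {overlap_rule!r}")
    return False


def classify_inheritance(
    patient_call: CnvCall,
    all_calls: Sequence[CnvCall],
    pedigrees: Sequence[PedigreeRecord],
    overlap_rule: str = "gene",
) -> InheritanceCall:
    """Classify one patient call as de novo / paternal / maternal / biparental,
    or not_determined when a required parent sample is missing."""
    ped_by_id = {p.sample_id: p for p in pedigrees}
    patient = ped_by_id.get(patient_call.sample_id)
    if patient is None:
        raise KeyError(f"sample {patient_call.sample_id} absent from pedigree")
    if not patient.affected:
        raise ValueError(f"sample {patient_call.sample_id} is not an affected patient")

    calls_by_sample: dict[str, list[CnvCall]] = {}
    for c in all_calls:
        calls_by_sample.setdefault(c.sample_id, []).append(c)

    def assayed(pid: Optional[str]) -> bool:
        return pid is not None and pid in ped_by_id

    father_ok = assayed(patient.father_id)
    mother_ok = assayed(patient.mother_id)

    siblings = [
        p
        for p in pedigrees
        if p.family_id == patient.family_id
        and not p.affected
        and p.sample_id not in (patient.father_id, patient.mother_id)
    ]
    sibling_checked = bool(siblings)
    sibling_absent = sibling_checked and not any(
        _carries(calls_by_sample.get(s.sample_id, ()), patient_call, overlap_rule)
        for s in siblings
    )

    if not (father_ok and mother_ok):
        pattern = "not_determined"
    else:
        in_father = _carries(
            calls_by_sample.get(patient.father_id, ()), patient_call, overlap_rule
        )
        in_mother = _carries(
            calls_by_sample.get(patient.mother_id, ()), patient_call, overlap_rule
        )
        if in_father and in_mother:
            pattern = "biparental"
        elif in_father:
            pattern = "paternal"
        elif in_mother:
            pattern = "maternal"
        else:
            pattern = "de_novo"
    return InheritanceCall(patient_call, pattern, sibling_checked, sibling_absent)


def detect_recessive(
    calls: Sequence[CnvCall], hom_ratio_threshold: float = HOM_RATIO_THRESHOLD
) -> list[CnvCall]:
    """Homozygous CNVs: deletion calls with observed/expected ratio strictly
    below the threshold (default 0.1)."""
    return [
        c for c in calls if c.type == "deletion" and c.reads_ratio < hom_ratio_threshold
    ]


def patient_unique_homozygous(
    hom_patient_calls: Sequence[CnvCall], hom_control_calls: Sequence[CnvCall]
) -> list[CnvCall]:
    """Drop patient homozygous calls whose gene is also homozygous in any
    control (gene-level matching); unique ones survive."""
    control_genes = {g for c in hom_control_calls for g in call_genes(c)}
    return [
        c
        for c in hom_patient_calls
        if not (set(call_genes(c)) & control_genes)
    ]
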