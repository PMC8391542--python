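"""Shared fixtures: tiny hand-built matrices and simulated mini-cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from cscnv.depth_caller import CnvCall
from cscnv.synthetic_cohort import (
    CohortSpec,
    ReadCountMatrix,
    TruthCnv,
    exon_id,
    generate_exon_targets,
    generate_pedigrees,
    simulate_read_counts,
)


def make_matrix(targets, sample_counts: dict[str, list[int]]) -> ReadCountMatrix:
    """Build a ReadCountMatrix from explicit per-sample count vectors."""
    frame = pd.DataFrame(sample_counts, index=[exon_id(t) for t in targets])
    return ReadCountMatrix(frame, list(targets))


def truth_to_calls(truth, targets) -> list[CnvCall]:
    """Perfect calls derived directly from a truth set (no caller noise)."""
    from cscnv.depth_caller import gene_exon_annotation

    ratios = {0: 0.0, 1: 0.5, 3: 1.5}
    return [
        CnvCall(
            sample_id=ev.sample_id,
            chrom=ev.chrom,
            start=ev.start,
            end=ev.end,
            type=ev.type,
            copy_state=ev.copy_number,
            bayes_factor=5.0,
            reads_ratio=ratios[ev.copy_number],
            exon_annotation=gene_exon_annotation(ev.chrom, ev.start, ev.end, targets),
        )
        for ev in truth
    ]


def make_call(sample="S1", chrom="1", start=1000, end=2000, type="deletion",
              copy_state=1, bayes_factor=5.0, reads_ratio=0.5,
              exon_annotation="GENE_1-2") -> CnvCall:
    return CnvCall(sample, chrom, start, end, type, copy_state,
                   bayes_factor, reads_ratio, exon_annotation)


@pytest.fixture(scope="session")
def small_targets():
    """20 genes of 4-8 exons; the workhorse target set for caller tests."""
    return generate_exon_targets(20, (4, 8), (100, 200), (500, 2000), seed=5)


@pytest.fixture(scope="session")
def quintet():
    """One quintet family: the patient plus 4 unaffected reference candidates."""
    spec = CohortSpec(1, 0, 0, 0, 0, mean_depth=100, depth_dispersion=0.01, seed=11)
    ped = generate_pedigrees(spec)
    return spec, ped


@pytest.fixture(scope="session")
def het_deletion_cohort(small_targets, quintet):
    """Counts with a 3-exon heterozygous deletion implanted in the patient."""
    spec, ped = quintet
    patient = next(p for p in ped if p.affected)
    seg = [t for t in small_targets if t.gene == "G0005"][:3]
    truth = [
        TruthCnv(patient.sample_id, seg[0].chrom, seg[0].start, seg[-1].end,
                 "deletion", 1, "de_novo")
    ]
    counts = simulate_read_counts(ped, small_targets, truth, spec)
    refs = [p.sample_id for p in ped if not p.affected]
    return counts, refs, patient.sample_id, truth
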