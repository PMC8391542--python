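"""Re-encoded result tables of the congenital-hemivertebra WES cohort study,
as runnable fixtures.

The published study reports three downstream call tables — the candidate-gene
screen, the patient-unique recessive CNVs, and the novel recurrently-hit
genes — together with the cohort's family composition (67 affected children,
125 unaffected relatives: 2 quintets, 14 quartets, 33 trios, 9 duos and 9
singletons).  This module rebuilds those tables as in-memory call sets,
pedigrees and population-frequency records so the whole filter /
classification / prioritization cascade can be exercised and its survivor
counts compared against the printed ones without any external data.

Only the printed rows (coordinates, Bayes factors, reads ratios, exon
annotations, frequencies) are taken from the study.  Everything the study
does not print — filler family identities, carrier assignments for the
recurrence table, per-call coordinates of the recurrent genes, the negative
decoy genes, and all qPCR cycle thresholds — is synthetic and is labelled as
such below.
"""

from __future__ import annotations

import itertools
from typing import Optional

from .depth_caller import CnvCall
from .prioritization import QpcrMeasurement
from .synthetic_cohort import PedigreeRecord, PopFreqRecord

__all__ = [
    "N_PATIENTS",
    "N_CONTROLS",
    "cohort_pedigrees",
    "candidate_table_calls",
    "recessive_table_calls",
    "dhx40_het_calls",
    "recurrent_gene_calls",
    "decoy_calls",
    "patient_calls",
    "control_calls",
    "population_frequencies",
    "qpcr_cts",
]

N_PATIENTS = 67
N_CONTROLS = 125

# family structure of the named patients, as implied by their printed
# inheritance patterns: quartet = parents + one sibling assayed, trio = both
# parents, duo = one parent, singleton = patient only
_QUARTET_NAMED = ["CS043", "CS048", "CS050"]
_TRIO_NAMED = ["CS018", "CS036", "CS047", "CS057", "CS071"]
_DUO_NAMED = ["CS004", "CS035"]
_SINGLETON_NAMED = ["CS033", "CS053", "CS059", "CS064", "CS078", "CS081"]

# synthetic filler patients completing the 2/14/33/9/9 family composition
_QUINTET_FILLER = [f"CS{i:03d}" for i in range(101, 103)]
_QUARTET_FILLER = [f"CS{i:03d}" for i in range(103, 114)]
_TRIO_FILLER = [f"CS{i:03d}" for i in range(114, 142)]
_DUO_FILLER = [f"CS{i:03d}" for i in range(142, 149)]
_SINGLETON_FILLER = [f"CS{i:03d}" for i in range(149, 152)]

_COMPLETE_FILLERS = _QUINTET_FILLER + _QUARTET_FILLER + _TRIO_FILLER


def cohort_pedigrees() -> list[PedigreeRecord]:
    """The 67-patient / 125-control pedigree with named patients placed in the
    family structures their printed inheritance patterns require."""
    records: list[PedigreeRecord] = []

    def family(pid: str, parents: int, sibs: int) -> None:
        father = f"{pid}F" if parents == 2 else None
        mother = f"{pid}M" if parents >= 1 else None
        records.append(PedigreeRecord(pid, pid, father, mother, "unknown", True))
        if father:
            records.append(PedigreeRecord(pid, father, None, None, "male", False))
        if mother:
            records.append(PedigreeRecord(pid, mother, None, None, "female", False))
        for k in range(sibs):
            records.append(
                PedigreeRecord(pid, f"{pid}S{k + 1}", father, mother, "unknown", False)
            )

    for pid in _QUINTET_FILLER:
        family(pid, 2, 2)
    for pid in _QUARTET_NAMED + _QUARTET_FILLER:
        family(pid, 2, 1)
    for pid in _TRIO_NAMED + _TRIO_FILLER:
        family(pid, 2, 0)
    for pid in _DUO_NAMED + _DUO_FILLER:
        family(pid, 1, 0)
    for pid in _SINGLETON_NAMED + _SINGLETON_FILLER:
        family(pid, 0, 0)
    return records


# ---------------------------------------------------------------------------
# Candidate-gene table (printed rows)
# ---------------------------------------------------------------------------

_TBX6_ANNOT_CS059 = (
    "SPN_2,AC009133.19_2-3,QPRT_1-4,C16orf54_2,ZG16_2-4,KIF22_1-13,MAZ_1-5,"
    "PRRT2_2-3,PAGR1_1-3,CTD-2574D22.6_1-2,MVP_2-15,CDIPT_6-2,SEZ6L2_16-1,"
    "ASPHD1_1-3,KCTD13_6-1,TMEM219_1-4,TAOK2_2-16,HIRIP3_7-1,INO80E_1-7,"
    "DOC2A_11-2,C16orf92_2-3,FAM57B_5-1,ALDOA_8-16,PPP4C_2-9,TBX6_9-2,"
    "YPEL3_4-1,GDPD3_10-1,MAPK3_8-1,CORO1A_2-3,CORO1A_4-10"
)
_TBX6_ANNOT_CS071 = (
    "NPIPL3_3-1,SPN_2,AC009133.19_2-3,QPRT_1-4,C16orf54_2,ZG16_3-4,KIF22_2-12,"
    "MAZ_1-5,PRRT2_2-3,PAGR1_1-3,CTD-2574D22.6_1-2,MVP_2-15,CDIPT_6-2,"
    "SEZ6L2_16-1,ASPHD1_1-3,KCTD13_6-1,TMEM219_1-4,TAOK2_2-16,HIRIP3_7-2,"
    "INO80E_1-7,DOC2A_11-2,C16orf92_2-3,FAM57B_5-1,ALDOA_8-16,PPP4C_2-9,"
    "TBX6_9-2,YPEL3_4-1,GDPD3_10-1,MAPK3_8-1,CORO1A_2-11,BOLA2B_3-1,"
    "SLX1A_1-5,SULT1A3_3-9,RP11-347C12.3_5-2"
)
_TBX6_ANNOT_CS078_81 = (
    "NPIPL3_1,SPN_2,AC009133.19_2-3,QPRT_1-4,C16orf54_2,ZG16_3-4,KIF22_2-12,"
    "MAZ_1-5,PRRT2_2-3,PAGR1_1-3,CTD-2574D22.6_1-2,MVP_2-15,CDIPT_6-2,"
    "SEZ6L2_16-1,ASPHD1_1-3,KCTD13_6-1,TMEM219_1-4,TAOK2_2-16,HIRIP3_7-2,"
    "INO80E_1-7,DOC2A_11-2,C16orf92_2-3,FAM57B_5-1,ALDOA_8-16,PPP4C_2-9,"
    "TBX6_9-2,YPEL3_4-1,GDPD3_10-1,MAPK3_8-1,CORO1A_2-10"
)

# (sample, chrom, start, end, BF, reads ratio, exon annotation)
_CANDIDATE_ROWS = [
    ("CS033", "1", 120_611_949, 120_612_020, 4.62, 0.657, "NOTCH2_1"),
    ("CS043", "1", 120_539_621, 120_612_020, 8.46, 0.722, "NOTCH2_1-4"),
    ("CS018", "21", 41_452_080, 41_452_267, 4.65, 0.429, "DSCAM_25"),
    ("CS036", "21", 41_452_080, 41_452_267, 6.02, 0.415, "DSCAM_25"),
    ("CS050", "21", 41_452_080, 41_452_267, 5.80, 0.468, "DSCAM_25"),
    ("CS053", "21", 41_452_080, 41_452_267, 5.45, 0.494, "DSCAM_25"),
    ("CS064", "21", 41_452_080, 41_452_267, 6.10, 0.463, "DSCAM_25"),
    ("CS048", "8", 51_503_440, 51_571_223, 6.37, 0.430, "SNTG1_13-15"),
    ("CS059", "16", 29_674_601, 30_199_897, 644.0, 0.555, _TBX6_ANNOT_CS059),
    ("CS071", "16", 29_495_011, 30_218_221, 754.0, 0.572, _TBX6_ANNOT_CS071),
    ("CS078", "16", 29_498_516, 30_199_897, 690.0, 0.578, _TBX6_ANNOT_CS078_81),
    ("CS081", "16", 29_498_516, 30_199_897, 645.0, 0.558, _TBX6_ANNOT_CS078_81),
]


def candidate_table_calls() -> list[CnvCall]:
    """The 12 printed candidate-gene CNV calls (all heterozygous deletions)."""
    return [
        CnvCall(s, chrom, start, end, "deletion", 1, bf, ratio, annot)
        for s, chrom, start, end, bf, ratio, annot in _CANDIDATE_ROWS
    ]


# ---------------------------------------------------------------------------
# Recessive table (printed rows); ratios not printed for the collapsed
# homozygous rows are encoded as 0
# ---------------------------------------------------------------------------

_RECESSIVE_ROWS = [
    ("CS047", "1", 148_261_458, 148_262_366, 5.27, 0.04, "NBPF20_98-99"),
    ("CS048", "9", 35_061, 35_519, 6.51, 0.0, "FAM138C_1-2"),
    ("CS004", "17", 57_656_834, 57_657_240, 5.38, 0.0, "DHX40_9-10"),
    ("CS035", "17", 57_656_834, 57_657_240, 4.91, 0.0, "DHX40_9-10"),
    ("CS043", "17", 57_656_834, 57_657_240, 6.00, 0.0, "DHX40_9-10"),
    ("CS050", "17", 57_656_834, 57_657_240, 7.23, 0.0, "DHX40_9-10"),
    ("CS053", "17", 57_656_834, 57_657_240, 7.02, 0.0, "DHX40_9-10"),
    ("CS057", "17", 57_656_834, 57_657_240, 6.29, 0.0, "DHX40_9-10"),
]


def recessive_table_calls() -> list[CnvCall]:
    """The 8 printed patient-unique homozygous deletion calls."""
    return [
        CnvCall(s, chrom, start, end, "deletion", 0, bf, ratio, annot)
        for s, chrom, start, end, bf, ratio, annot in _RECESSIVE_ROWS
    ]


def dhx40_het_calls() -> list[CnvCall]:
    """Synthetic carriers for the four additional heterozygous DHX40 CNVs
    (the study reports their count and size range, not their rows)."""
    sizes = [107, 500, 1200, 2354]
    calls = []
    for k, (pid, size) in enumerate(zip(["CS114", "CS115", "CS116", "CS117"], sizes)):
        start = 57_656_900 + 10 * k
        calls.append(
            CnvCall(pid, "17", start, start + size, "deletion", 1,
                    4.0 + 0.5 * k, 0.47 + 0.01 * k, "DHX40_9")
        )
    return calls


# ---------------------------------------------------------------------------
# Recurrent ("novel") genes: printed per-gene counts, synthetic carriers
# ---------------------------------------------------------------------------

# gene -> (chrom, type, n_patients, n_controls, size range)
_RECURRENT_GENES: dict[str, tuple[str, str, int, int, tuple[int, int]]] = {
    "LRRC40": ("1", "deletion", 4, 0, (30_080, 383_938)),
    "SCN7A": ("2", "deletion", 4, 0, (544, 11_914)),
    "MME": ("3", "deletion", 4, 0, (279, 55_232)),
    "NAE1": ("16", "deletion", 4, 0, (6_724, 71_803)),
    "GMCL1": ("2", "deletion", 5, 1, (11_694, 24_032)),
    "MYSM1": ("1", "deletion", 4, 1, (190, 10_053)),
    "RASA2": ("3", "deletion", 4, 1, (2_892, 100_149)),
    "NSMAF": ("8", "deletion", 4, 1, (203, 12_325)),
    "MNS1": ("15", "deletion", 4, 1, (52_610, 323_156)),
    "PHKB": ("16", "deletion", 4, 1, (7_697, 99_254)),
    "SPO11": ("20", "deletion", 4, 1, (730, 33_608)),
    "ABCA6": ("17", "duplication", 4, 1, (560, 13_580)),
}

_GENE_BASE_POS = {g: 1_000_000 + 3_000_000 * i for i, g in enumerate(_RECURRENT_GENES)}


def _make_call(sample: str, gene: str, chrom: str, cnv_type: str, k: int,
               size: int) -> CnvCall:
    start = _GENE_BASE_POS[gene] + 500_000 * k
    copy = 3 if cnv_type == "duplication" else 1
    ratio = 1.5 if cnv_type == "duplication" else 0.5
    return CnvCall(sample, chrom, start, start + size, cnv_type, copy,
                   4.0 + 0.3 * k, ratio, f"{gene}_1-3")


def recurrent_gene_calls() -> tuple[list[CnvCall], list[CnvCall]]:
    """Synthetic patient and control carrier calls reproducing the printed
    per-gene recurrence counts (each gene gets >=1 complete-family carrier)."""
    patient_rows: list[CnvCall] = []
    control_rows: list[CnvCall] = []
    filler = itertools.cycle(_COMPLETE_FILLERS)
    control_pool = iter(f"CS{i:03d}M" for i in range(118, 142))
    for gene, (chrom, cnv_type, n_pat, n_ctl, (lo, hi)) in _RECURRENT_GENES.items():
        for k in range(n_pat):
            size = lo if k == 0 else (hi if k == n_pat - 1 else (lo + hi) // 2)
            patient_rows.append(_make_call(next(filler), gene, chrom, cnv_type, k, size))
        for _ in range(n_ctl):
            control_rows.append(
                _make_call(next(control_pool), gene, chrom, cnv_type, 90, (lo + hi) // 2)
            )
    # the heterozygous DHX40 carrier among controls (printed control count 1)
    control_rows.append(
        CnvCall("CS140M", "17", 57_656_900, 57_657_007, "deletion", 1, 4.4, 0.49,
                "DHX40_9")
    )
    return patient_rows, control_rows


# ---------------------------------------------------------------------------
# Synthetic negative controls for the enrichment rule
# ---------------------------------------------------------------------------

def decoy_calls() -> tuple[list[CnvCall], list[CnvCall]]:
    """Synthetic genes that must each fail exactly one prioritization rule:

    DECOYHOM   homozygous in one patient and one control -> not patient-unique
    DECOY3P    three patient carriers -> fails the "more than three" rule
    DECOYCTRL  five patients but two controls (1.6% > 1%) -> control-excluded
    DECOYCOM   four patients but population frequency 0.02 -> frequency-excluded
    DECOYLATE  four carriers, none from a complete family -> never discovered
    """

    def call(sample: str, gene: str, chrom: str, start: int, ratio: float,
             copy: int) -> CnvCall:
        return CnvCall(sample, chrom, start, start + 1_000, "deletion", copy,
                       5.0, ratio, f"{gene}_1-2")

    patients = [
        call("CS128", "DECOYHOM", "4", 1_000_000, 0.0, 0),
        *[call(s, "DECOY3P", "4", 2_000_000, 0.5, 1)
          for s in ["CS130", "CS131", "CS132"]],
        *[call(s, "DECOYCTRL", "4", 3_000_000, 0.5, 1)
          for s in ["CS133", "CS134", "CS135", "CS136", "CS137"]],
        *[call(s, "DECOYCOM", "4", 4_000_000, 0.5, 1)
          for s in ["CS104", "CS105", "CS106", "CS107"]],
        *[call(s, "DECOYLATE", "4", 5_000_000, 0.5, 1)
          for s in ["CS142", "CS143", "CS149", "CS150"]],
    ]
    controls = [
        call("CS129M", "DECOYHOM", "4", 1_000_000, 0.0, 0),
        call("CS138M", "DECOYCTRL", "4", 3_000_000, 0.5, 1),
        call("CS139M", "DECOYCTRL", "4", 3_000_000, 0.5, 1),
    ]
    return patients, controls


# ---------------------------------------------------------------------------
# Full cohort call sets
# ---------------------------------------------------------------------------

def patient_calls(include_decoys: bool = True) -> list[CnvCall]:
    """Every patient call of the reconstructed cohort."""
    recurrent_pat, _ = recurrent_gene_calls()
    calls = (
        candidate_table_calls()
        + recessive_table_calls()
        + dhx40_het_calls()
        + recurrent_pat
    )
    if include_decoys:
        calls += decoy_calls()[0]
    return calls


def control_calls(include_decoys: bool = True) -> list[CnvCall]:
    """Every control call: the carrier father behind the printed paternal
    DSCAM call, a second synthetic DSCAM carrier (the gene is absent from the
    printed recurrence table, so its control fraction must exceed 1%), the
    recurrence-table control carriers, and the decoy controls."""
    calls = [
        CnvCall("CS050F", "21", 41_452_080, 41_452_267, "deletion", 1, 5.1, 0.47,
                "DSCAM_25"),
        CnvCall("CS103M", "21", 41_452_080, 41_452_267, "deletion", 1, 4.8, 0.51,
                "DSCAM_25"),
    ]
    calls += recurrent_gene_calls()[1]
    if include_decoys:
        calls += decoy_calls()[1]
    return calls


# ---------------------------------------------------------------------------
# Population frequencies (printed columns; decoy records synthetic)
# ---------------------------------------------------------------------------

_DGV_N = 1_000
_GNOMAD_N = 10_000

# gene -> (DGV freq | None, DGV sample size, gnomAD freq | None, East-Asia freq | None)
_POPFREQ: dict[str, tuple[Optional[float], int, Optional[float], Optional[float]]] = {
    "NOTCH2": (0.0037, _DGV_N, 0.00037, 0.0),
    "DSCAM": (0.00049, _DGV_N, None, None),
    "SNTG1": (0.0002, _DGV_N, 0.000046, 0.0),
    "TBX6": (0.0005, _DGV_N, 0.0001462, 0.0),
    "NBPF20": (0.0, _DGV_N, 0.0, 0.0),
    "FAM138C": (0.0074, _DGV_N, None, None),
    "DHX40": (0.0000922, _DGV_N, 0.0025, 0.008152),
    "LRRC40": (0.009556907, _DGV_N, 0.0000461, 0.0),
    "SCN7A": (0.002257336, _DGV_N, 0.0000461, 0.0),
    "MME": (0.000798722, _DGV_N, 0.0000462, 0.0),
    # the only DGV-like record for NAE1 comes from an under-powered survey
    "NAE1": (0.03, 50, 0.0, 0.0),
    "GMCL1": (0.001303781, _DGV_N, 0.0000479, 0.0),
    "MYSM1": (0.0000922, _DGV_N, 0.0000461, 0.0004139),
    "RASA2": (0.00086881, _DGV_N, 0.0, 0.0),
    "NSMAF": (0.001145475, _DGV_N, 0.0, 0.0),
    "MNS1": (0.00518807, _DGV_N, 0.0000922, 0.0),
    "PHKB": (0.001198083, _DGV_N, 0.0000481, 0.0),
    "SPO11": (0.00064226, _DGV_N, 0.0, 0.0),
    "ABCA6": (0.0009219, _DGV_N, 0.0, 0.0),
    # synthetic decoys
    "DECOYHOM": (0.0, _DGV_N, None, None),
    "DECOY3P": (0.0, _DGV_N, None, None),
    "DECOYCTRL": (0.0, _DGV_N, None, None),
    "DECOYCOM": (0.02, _DGV_N, None, None),
    "DECOYLATE": (0.0, _DGV_N, None, None),
}


def _cogenes_16p11() -> set[str]:
    genes: set[str] = set()
    for annot in (_TBX6_ANNOT_CS059, _TBX6_ANNOT_CS071, _TBX6_ANNOT_CS078_81):
        for token in annot.split(","):
            genes.add(token.rsplit("_", 1)[0])
    genes.discard("TBX6")
    return genes


def population_frequencies() -> list[PopFreqRecord]:
    """DGV-like and gnomAD-like records for every gene of the cohort tables.

    Genes of the recurrent microdeletion region that co-occur on the TBX6
    calls receive a common (0.05) frequency, reflecting that only TBX6 itself
    survives the frequency filter there.
    """
    records: list[PopFreqRecord] = []
    for gene, (dgv, dgv_n, gnomad, east) in _POPFREQ.items():
        if dgv is not None:
            records.append(PopFreqRecord(gene, "DGV-like", dgv_n, dgv))
        if gnomad is not None:
            records.append(PopFreqRecord(gene, "gnomAD-like", _GNOMAD_N, gnomad, east))
    for gene in sorted(_cogenes_16p11()):
        records.append(PopFreqRecord(gene, "DGV-like", _DGV_N, 0.05))
    return records


# ---------------------------------------------------------------------------
# qPCR fixture (synthetic cycle thresholds; the study prints none)
# ---------------------------------------------------------------------------

def qpcr_cts() -> list[QpcrMeasurement]:
    """Synthetic triplicate-mean Ct values for the validated deletion loci.

    Each target locus is measured against the reference locus P1 with an
    unaffected calibrator sample; carriers of a heterozygous deletion run one
    cycle late at the target, giving 2^-ΔΔCt = 0.5 and copy estimate 1.
    """
    rows = []
    for locus, carrier in [("NOTCH2", "CS043"), ("DSCAM", "CS018"), ("SNTG1", "CS048")]:
        rows.append(QpcrMeasurement("CTRL1", locus, "P1", 25.0, 25.0, "CTRL1"))
        rows.append(QpcrMeasurement(carrier, locus, "P1", 26.0, 25.0, "CTRL1"))
    return rows
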