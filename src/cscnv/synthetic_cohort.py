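"""Synthetic family-structured exome cohorts with implanted CNVs.

Generates everything the downstream caller and filters consume, without any
external download: pedigrees mirroring a hemivertebra cohort (affected child
plus unaffected parents/siblings), exon capture targets, overdispersed
per-exon read counts with implanted deletions/duplications, and companion
population-frequency tables in which the implanted variants are rare.

Coordinates are 0-based half-open throughout, so an interval's size in bp is
always ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExonTarget",
    "PedigreeRecord",
    "CohortSpec",
    "TruthCnv",
    "PopFreqRecord",
    "ReadCountMatrix",
    "exon_id",
    "generate_pedigrees",
    "generate_exon_targets",
    "implant_cnvs",
    "simulate_read_counts",
    "generate_popfreq_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ExonTarget:
    """One captured exon: the unit of calling and of gene annotation."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_index: int  # 1-based exon number within the gene

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"exon target {self.gene}_{self.exon_index}: end must exceed start"
            )
        if self.exon_index < 1:
            raise ValueError("exon_index is 1-based and must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


def exon_id(target: ExonTarget) -> str:
    """Stable row identifier used in count matrices: ``GENE_exonIndex``."""
    return f"{target.gene}_{target.exon_index}"


@dataclass(frozen=True)
class PedigreeRecord:
    """One cohort member. Affected children are patients, everyone else a control."""

    family_id: str
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female" | "unknown"
    affected: bool


@dataclass(frozen=True)
class CohortSpec:
    """Family composition and coverage model of a simulated cohort.

    ``mean_depth`` is the expected read count of a diploid exon of average
    length; counts scale proportionally with exon length.  ``depth_dispersion``
    is the negative-binomial overdispersion (variance = mu + d*mu^2); 0 gives
    Poisson counts.  ``leakage`` is a mis-mapping rate: the residual coverage
    fraction retained at homozygously deleted exons, so observed/expected
    ratios near but not exactly 0 can be exercised.
    """

    n_quintets: int = 2
    n_quartets: int = 14
    n_trios: int = 33
    n_duos: int = 9
    n_singletons: int = 9
    mean_depth: float = 100.0
    depth_dispersion: float = 0.01
    leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_quintets", "n_quartets", "n_trios", "n_duos", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.depth_dispersion < 0 or self.leakage < 0:
            raise ValueError("depth_dispersion and leakage must be >= 0")


@dataclass(frozen=True)
class TruthCnv:
    """Ground-truth implanted event, used by recovery tests."""

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str  # "deletion" | "duplication"
    copy_number: int  # 0 or 1 for deletions, 3 for duplications
    origin: str  # "de_novo" | "paternal" | "maternal" | "biparental"

    def __post_init__(self) -> None:
        if self.type == "deletion" and self.copy_number not in (0, 1):
            raise ValueError("deletion copy_number must be 0 or 1")
        if self.type == "duplication" and self.copy_number != 3:
            raise ValueError("duplication copy_number must be 3")


@dataclass(frozen=True)
class PopFreqRecord:
    """One database record of heterozygous-loss frequency for a gene."""

    gene: str
    database: str  # "DGV-like" | "gnomAD-like"
    sample_size: int
    freq_het_loss: float
    freq_het_loss_east_asia: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_het_loss <= 1.0:
            raise ValueError("freq_het_loss must lie in [0,1]")
        if self.freq_het_loss_east_asia is not None and not (
            0.0 <= self.freq_het_loss_east_asia <= 1.0
        ):
            raise ValueError("freq_het_loss_east_asia must lie in [0,1]")
        if self.sample_size < 0:
            raise ValueError("sample_size must be >= 0")


@dataclass
class ReadCountMatrix:
    """Per-exon integer read counts (rows: exons in target order, cols: samples)."""

    counts: pd.DataFrame
    targets: list[ExonTarget]

    def __post_init__(self) -> None:
        expected = [exon_id(t) for t in self.targets]
        if list(self.counts.index) != expected:
            raise ValueError("count matrix rows must match targets in order")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def _family(family_id: str, n_members: int, with_parents: int, n_sibs: int,
            rng: np.random.Generator) -> list[PedigreeRecord]:
    """Build one nuclear family: affected child first, then parents, then sibs."""
    records: list[PedigreeRecord] = []
    patient = f"{family_id}P"
    father = f"{family_id}F" if with_parents >= 1 else None
    mother = f"{family_id}M" if with_parents >= 1 else None
    # duos keep the mother only; family files encode the absent father as "0"
    if with_parents == 1:
        father = None
    child_sex = "male" if rng.random() < 0.5 else "female"
    records.append(PedigreeRecord(family_id, patient, father, mother, child_sex, True))
    if father is not None:
        records.append(PedigreeRecord(family_id, father, None, None, "male", False))
    if mother is not None:
        records.append(PedigreeRecord(family_id, mother, None, None, "female", False))
    for k in range(n_sibs):
        sex = "male" if rng.random() < 0.5 else "female"
        records.append(
            PedigreeRecord(family_id, f"{family_id}S{k + 1}", father, mother, sex, False)
        )
    assert len(records) == n_members
    return records


def generate_pedigrees(spec: CohortSpec) -> list[PedigreeRecord]:
    """Build the cohort's pedigree: one affected child per family.

    Quintet = patient + both parents + 2 unaffected siblings; quartet drops one
    sibling; trio keeps both parents only; duo keeps a single parent (the
    mother); singleton is the patient alone.
    """
    rng = np.random.default_rng(spec.seed)
    plan = (
        [("Q5", 5, 2, 2)] * spec.n_quintets
        + [("Q4", 4, 2, 1)] * spec.n_quartets
        + [("T3", 3, 2, 0)] * spec.n_trios
        + [("D2", 2, 1, 0)] * spec.n_duos
        + [("S1", 1, 0, 0)] * spec.n_singletons
    )
    records: list[PedigreeRecord] = []
    for i, (tag, n_members, with_parents, n_sibs) in enumerate(plan, start=1):
        records.extend(_family(f"F{i:03d}{tag}", n_members, with_parents, n_sibs, rng))
    return records


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

def generate_exon_targets(
    n_genes: int,
    exons_per_gene_range: tuple[int, int] = (2, 30),
    exon_len_range: tuple[int, int] = (80, 300),
    gap_range: tuple[int, int] = (500, 5000),
    seed: int = 0,
) -> list[ExonTarget]:
    """Lay out non-overlapping gene/exon targets along autosomes.

    Genes are placed round-robin over chromosomes 1..22 with a running cursor
    per chromosome, so targets are sorted and disjoint by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (exons_per_gene_range, exon_len_range, gap_range):
        if lo < 1 or hi < lo:
            raise ValueError("ranges must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    n_chroms = min(n_genes, 22)
    cursors = {str(c): 10_000 for c in range(1, n_chroms + 1)}
    targets: list[ExonTarget] = []
    for g in range(n_genes):
        chrom = str(g % n_chroms + 1)
        gene = f"G{g + 1:04d}"
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        pos = cursors[chrom] + int(rng.integers(20_000, 50_000))  # intergenic spacer
        for e in range(1, n_exons + 1):
            length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            targets.append(ExonTarget(chrom, pos, pos + length, gene, e))
            pos += length + int(rng.integers(gap_range[0], gap_range[1] + 1))
        cursors[chrom] = pos
    targets.sort(key=lambda t: (int(t.chrom), t.start))
    return targets


def _genes_in_order(targets: Sequence[ExonTarget]) -> list[str]:
    seen: dict[str, None] = {}
    for t in targets:
        seen.setdefault(t.gene, None)
    return list(seen)


# ---------------------------------------------------------------------------
# CNV implantation
# ---------------------------------------------------------------------------

def implant_cnvs(
    pedigrees: Sequence[PedigreeRecord],
    targets: Sequence[ExonTarget],
    n_events: int,
    het_fraction: float = 0.8,
    de_novo_fraction: float = 0.5,
    seed: int = 0,
    max_exons: int = 30,
) -> list[TruthCnv]:
    """Implant CNV events into patients, one event per distinct gene.

    Each event spans a contiguous run of whole exons.  Heterozygous events are
    deletions or duplications (copy 1 or 3) and may be inherited, in which case
    the same event is also placed in one parent's truth set.  Homozygous
    deletions (copy 0) are implanted in patients only, as de novo events, to
    support recessive-recovery tests.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    genes = _genes_in_order(targets)
    if n_events > len(genes):
        raise ValueError(
            f"n_events={n_events} exceeds available disjoint gene slots ({len(genes)})"
        )
    by_gene = {
        g: sorted((t for t in targets if t.gene == g), key=lambda t: t.exon_index)
        for g in genes
    }
    ped_by_id = {p.sample_id: p for p in pedigrees}
    patients = [p for p in pedigrees if p.affected]
    if not patients:
        raise ValueError("pedigree contains no affected samples")

    rng = np.random.default_rng(seed)
    chosen_genes = list(rng.choice(genes, size=n_events, replace=False))
    truth: list[TruthCnv] = []
    for gene in chosen_genes:
        exons = by_gene[gene]
        patient = patients[int(rng.integers(len(patients)))]
        span = int(rng.integers(1, min(max_exons, len(exons)) + 1))
        first = int(rng.integers(0, len(exons) - span + 1))
        seg = exons[first:first + span]
        chrom, start, end = seg[0].chrom, seg[0].start, seg[-1].end

        het = rng.random() < het_fraction
        if het:
            if rng.random() < 0.5:
                cnv_type, copy = "deletion", 1
            else:
                cnv_type, copy = "duplication", 3
        else:
            cnv_type, copy = "deletion", 0

        origin = "de_novo"
        if het and rng.random() >= de_novo_fraction:
            parent_ids = [
                pid
                for pid in (patient.father_id, patient.mother_id)
                if pid is not None and pid in ped_by_id
            ]
            if parent_ids:
                parent_id = parent_ids[int(rng.integers(len(parent_ids)))]
                origin = (
                    "paternal" if parent_id == patient.father_id else "maternal"
                )
                truth.append(
                    TruthCnv(parent_id, chrom, start, end, cnv_type, copy, "de_novo")
                )
        truth.append(
            TruthCnv(patient.sample_id, chrom, start, end, cnv_type, copy, origin)
        )
    return truth


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def _copy_numbers(
    sample_id: str, targets: Sequence[ExonTarget], truth: Iterable[TruthCnv]
) -> np.ndarray:
    copies = np.full(len(targets), 2, dtype=float)
    for ev in truth:
        if ev.sample_id != sample_id:
            continue
        for i, t in enumerate(targets):
            if t.chrom == ev.chrom and t.start < ev.end and ev.start < t.end:
                copies[i] = ev.copy_number
    return copies


def simulate_read_counts(
    pedigrees: Sequence[PedigreeRecord],
    targets: Sequence[ExonTarget],
    truth: Sequence[TruthCnv],
    spec: CohortSpec,
) -> ReadCountMatrix:
    """Draw negative-binomial exon counts for every cohort member.

    The expected count of an exon at copy number c is
    ``mean_depth * (c/2) * (exon_length / mean_exon_length)``; homozygous
    losses retain ``leakage * mean_depth`` expected coverage.  Dispersion d
    gives variance mu + d*mu^2 via a Poisson-gamma mixture, recovering plain
    Poisson at d = 0.
    """
    rng = np.random.default_rng(spec.seed + 1)
    lengths = np.array([t.length for t in targets], dtype=float)
    length_factor = lengths / lengths.mean()
    d = spec.depth_dispersion

    columns: dict[str, np.ndarray] = {}
    for person in pedigrees:
        copies = _copy_numbers(person.sample_id, targets, truth)
        frac = np.maximum(copies / 2.0, spec.leakage)
        mu = spec.mean_depth * frac * length_factor
        if d > 0:
            lam = rng.gamma(shape=1.0 / d, scale=mu * d)
        else:
            lam = mu
        columns[person.sample_id] = rng.poisson(lam)
    frame = pd.DataFrame(columns, index=[exon_id(t) for t in targets])
    return ReadCountMatrix(frame, list(targets))


# ---------------------------------------------------------------------------
# Population-frequency tables
# ---------------------------------------------------------------------------

def generate_popfreq_table(
    targets: Sequence[ExonTarget],
    implanted_genes: Iterable[str],
    background_af_range: tuple[float, float] = (0.02, 0.2),
    seed: int = 0,
    common_fraction: float = 0.2,
    small_cohort_fraction: float = 0.1,
) -> list[PopFreqRecord]:
    """Emit DGV-like and gnomAD-like frequency records for every gene.

    Implanted genes are always rare (< 0.01) in eligible records.  A
    ``common_fraction`` of the remaining background genes receive frequencies
    above 0.01 so the allele-frequency exclusion is exercised, and a
    ``small_cohort_fraction`` of genes additionally get a high-frequency record
    whose sample size is below 100, which the filters must ignore.
    """
    lo, hi = background_af_range
    if not (0.01 < lo <= hi <= 1.0):
        raise ValueError("background_af_range must lie within (0.01, 1]")
    rng = np.random.default_rng(seed)
    implanted = set(implanted_genes)
    records: list[PopFreqRecord] = []
    for gene in _genes_in_order(targets):
        if gene in implanted:
            dgv = float(rng.uniform(0.0, 0.005))
            gnomad = float(rng.uniform(0.0, 0.005))
        elif rng.random() < common_fraction:
            dgv = float(rng.uniform(lo, hi))
            gnomad = float(rng.uniform(lo, hi))
        else:
            dgv = float(rng.uniform(0.0, 0.009))
            gnomad = float(rng.uniform(0.0, 0.009))
        east_asia = None if rng.random() < 0.3 else float(min(gnomad, 0.009)
                                                         if gene in implanted else gnomad)
        records.append(PopFreqRecord(gene, "DGV-like", 1000, dgv))
        records.append(PopFreqRecord(gene, "gnomAD-like", 10000, gnomad, east_asia))
        if gene not in implanted and rng.random() < small_cohort_fraction:
            # under-powered survey record; ineligible for filtering decisions
            records.append(
                PopFreqRecord(gene, "DGV-like", 50, float(rng.uniform(0.02, 0.5)))
            )
    return records
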