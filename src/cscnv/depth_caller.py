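"""Read-depth CNV calling from exon counts against an aggregated reference set.

The model follows the standard exome read-depth approach: for each exon the
test sample's count x is compared with the pooled reference count r through a
beta-binomial on x given n = x + r, where the expected fraction phi of test
reads scales with the copy number c as

    phi'(c) = (c/2) * phi / ((c/2) * phi + (1 - phi))

so c = 2 leaves phi unchanged, a heterozygous deletion (c = 1) shifts the
expected fraction down, and a single-copy gain (c = 3) shifts it up.  A
3-state first-order chain over ordered exons (deletion / diploid /
duplication) is decoded by the Viterbi maximum-probability path; maximal
non-diploid runs become calls, each annotated with a log10 Bayes factor
against the diploid null and an observed/expected reads ratio.  Homozygous
versus heterozygous deletion is decided afterwards from the segment ratio
against the 0.1 discriminator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import betabinom

from .synthetic_cohort import ExonTarget, ReadCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceProfile",
    "CnvCall",
    "DEFAULT_TRANSITION_PROB",
    "HOM_RATIO_THRESHOLD",
    "LEAKAGE_COPY_FLOOR",
    "RHO_FLOOR",
    "build_reference",
    "shifted_phi",
    "emission_loglik",
    "viterbi_path",
    "call_cnvs",
    "compute_bayes_factor",
    "compute_reads_ratio",
    "gene_exon_annotation",
    "call_genes",
]

#: per-exon-boundary probability of switching copy state in the decoder
DEFAULT_TRANSITION_PROB = 1e-4
#: segment observed/expected ratio below which a deletion is called homozygous
HOM_RATIO_THRESHOLD = 0.1
#: effective copy number substituted for c=0 so stray (mis-mapped) reads keep a
#: finite likelihood; observed homozygous losses show small nonzero ratios
LEAKAGE_COPY_FLOOR = 0.02
#: lower bound for the fitted beta-binomial overdispersion
RHO_FLOOR = 1e-4

_STATES = ("deletion", "diploid", "duplication")
_STATE_COPY = (1, 2, 3)
_DIPLOID = 1  # index into _STATES


@dataclass
class ReferenceProfile:
    """Aggregated reference coverage and the fitted emission parameters.

    ``phi`` is the expected fraction of test reads among test + reference
    reads per exon for a test sample of typical total depth; callers rescale
    it to the actual test sample's depth.  Exons where the pooled reference
    has zero coverage are masked and excluded from decoding.
    """

    reference_sample_ids: list[str]
    ref_count: np.ndarray
    phi: np.ndarray
    rho: float
    mask: np.ndarray  # True where the exon is usable

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        usable_phi = self.phi[self.mask]
        if usable_phi.size and not ((usable_phi > 0) & (usable_phi < 1)).all():
            raise ValueError("phi must lie in (0,1) on unmasked exons")


@dataclass(frozen=True)
class CnvCall:
    """One called CNV segment; the row type of every downstream report."""

    sample_id: str
    chrom: str
    start: int
    end: int
    type: str  # "deletion" | "duplication"
    copy_state: int  # 0 | 1 | 3
    bayes_factor: float  # log10 likelihood ratio vs the diploid null
    reads_ratio: float  # observed / expected segment reads
    exon_annotation: str  # "GENE_a-b" per overlapped gene, comma-joined

    @property
    def size(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if self.reads_ratio < 0:
            raise ValueError("reads_ratio must be >= 0")
        if self.type == "deletion" and self.copy_state not in (0, 1):
            raise ValueError("deletion copy_state must be 0 or 1")
        if self.type == "duplication" and self.copy_state != 3:
            raise ValueError("duplication copy_state must be 3")


def call_genes(call: CnvCall) -> list[str]:
    """Gene symbols parsed from a call's exon annotation (may be empty)."""
    if not call.exon_annotation:
        return []
    genes: list[str] = []
    for token in call.exon_annotation.split(","):
        token = token.strip()
        if token:
            genes.append(token.rsplit("_", 1)[0])
    return genes


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def build_reference(counts: ReadCountMatrix, reference_ids: Sequence[str]) -> ReferenceProfile:
    """Pool reference samples and fit the emission parameters.

    ``ref_count`` is the exon-wise sum over the reference samples.  ``phi`` is
    derived from total depths: a test sample of total depth T against a pool
    of total depth R expects fraction T / (T + R) of the combined reads at
    every exon (both sides scale with the same per-exon capture efficiency).
    The overdispersion ``rho`` is fitted by the method of moments on
    leave-one-out reference-vs-rest splits, floored at 1e-4.
    """
    if len(reference_ids) < 1:
        raise ValueError("at least one reference sample is required")
    unknown = [s for s in reference_ids if s not in counts.counts.columns]
    if unknown:
        raise KeyError(f"unknown reference sample id(s): {', '.join(unknown)}")

    ref = counts.counts[list(reference_ids)].to_numpy(dtype=float)
    ref_count = ref.sum(axis=1)
    mask = ref_count > 0
    n_masked = int((~mask).sum())
    if n_masked:
        logger.warning("masking %d exon(s) with zero reference coverage", n_masked)

    test_ids = [s for s in counts.sample_ids if s not in set(reference_ids)]
    pool_ids = test_ids if test_ids else list(reference_ids)
    r_total = ref_count[mask].sum()
    t_typical = counts.counts[pool_ids].to_numpy(dtype=float)[mask].sum(axis=0).mean()
    phi_scalar = t_typical / (t_typical + r_total)
    phi = np.full(len(ref_count), phi_scalar)

    rho = _fit_rho(ref, mask)
    return ReferenceProfile(list(reference_ids), ref_count, phi, rho, mask)


def _fit_rho(ref: np.ndarray, mask: np.ndarray) -> float:
    """Method-of-moments overdispersion from reference-vs-rest splits.

    For sample j at exon i, x ~ BetaBin(n_i, p_j) with n_i the pooled count
    and p_j = T_j / T_all; Var(x) = n p (1-p) (1 + (n-1) rho), so
    rho = (mean standardized squared residual - 1) / (mean n - 1).
    """
    if ref.shape[1] < 2:
        return RHO_FLOOR
    totals = ref[mask].sum(axis=0)
    n = ref[mask].sum(axis=1)
    z_all: list[np.ndarray] = []
    for j in range(ref.shape[1]):
        p = totals[j] / totals.sum()
        x = ref[mask, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - n * p) ** 2 / (n * p * (1 - p))
        z_all.append(z[np.isfinite(z)])
    z = np.concatenate(z_all)
    if z.size == 0 or n.mean() <= 1:
        return RHO_FLOOR
    rho = (z.mean() - 1.0) / (n.mean() - 1.0)
    return float(max(rho, RHO_FLOOR))


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

def shifted_phi(phi: float | np.ndarray, copy_state: float) -> float | np.ndarray:
    """Expected test-read fraction at copy number c: (c/2)phi / ((c/2)phi + 1 - phi)."""
    c = LEAKAGE_COPY_FLOOR if copy_state == 0 else copy_state
    w = (c / 2.0) * phi
    return w / (w + (1.0 - phi))


def emission_loglik(
    x: float | np.ndarray,
    r: float | np.ndarray,
    phi: float | np.ndarray,
    rho: float,
    copy_state: int,
) -> float | np.ndarray:
    """Beta-binomial log P(x | n = x + r) under the given copy state."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(x < 0) or np.any(r < 0):
        raise ValueError("counts must be >= 0")
    if np.any(x + r == 0):
        raise ValueError("x and r must not both be 0")
    rho = max(float(rho), 1e-8)
    p = shifted_phi(np.asarray(phi, dtype=float), copy_state)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    out = betabinom.logpmf(x.astype(int), (x + r).astype(int), a, b)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

#: probability of remaining in a non-diploid state at the next exon; the
#: complement (minus the cross-type probability) returns to diploid, so
#: segment boundaries are cheap to close and a CNV is penalised once, on entry
CNV_STAY_PROB = 0.7


def _log_transition_matrix(transition_prob: float) -> np.ndarray:
    t = transition_prob
    if not 0 < t < 0.5:
        raise ValueError("transition_prob must lie in (0, 0.5)")
    stay = CNV_STAY_PROB
    m = np.array(
        [
            [stay, 1.0 - stay - t, t],  # deletion -> (del, dip, dup)
            [t, 1.0 - 2.0 * t, t],      # diploid  -> (del, dip, dup)
            [t, 1.0 - stay - t, stay],  # duplication
        ]
    )
    return np.log(m)


def viterbi_path(emissions: np.ndarray, transition_prob: float) -> np.ndarray:
    """Maximum-probability state path over one chromosome's ordered exons.

    ``emissions``: array (n_exons, 3) of log-likelihoods for the states
    (deletion, diploid, duplication).  The initial distribution matches one
    transition step out of the diploid state.
    """
    n = emissions.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    log_t = _log_transition_matrix(transition_prob)
    init = log_t[_DIPLOID]  # start as if preceded by a diploid exon
    score = init + emissions[0]
    back = np.zeros((n, 3), dtype=int)
    for i in range(1, n):
        cand = score[:, None] + log_t  # cand[prev, cur]
        back[i] = cand.argmax(axis=0)
        score = cand.max(axis=0) + emissions[i]
    path = np.zeros(n, dtype=int)
    path[-1] = int(score.argmax())
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def gene_exon_annotation(
    chrom: str, start: int, end: int, targets: Sequence[ExonTarget]
) -> str:
    """Annotation string "GENE_a-b" per gene with >=1 exon overlapping [start, end)."""
    per_gene: dict[str, list[int]] = {}
    order: list[str] = []
    for t in targets:
        if t.chrom == chrom and t.start < end and start < t.end:
            if t.gene not in per_gene:
                per_gene[t.gene] = []
                order.append(t.gene)
            per_gene[t.gene].append(t.exon_index)
    parts = []
    for gene in order:
        idx = sorted(per_gene[gene])
        parts.append(f"{gene}_{idx[0]}" if idx[0] == idx[-1] else f"{gene}_{idx[0]}-{idx[-1]}")
    return ",".join(parts)


def call_cnvs(
    test_sample: str,
    counts: ReadCountMatrix,
    profile: ReferenceProfile,
    transition_prob: float = DEFAULT_TRANSITION_PROB,
    hom_ratio_threshold: float = HOM_RATIO_THRESHOLD,
) -> list[CnvCall]:
    """Call CNVs for one test sample by decoding the 3-state chain per chromosome."""
    if test_sample in profile.reference_sample_ids:
        logger.warning(
            "test sample %s is part of the reference set; calling anyway", test_sample
        )
    if test_sample not in counts.counts.columns:
        raise KeyError(f"unknown sample id: {test_sample}")

    x_all = counts.counts[test_sample].to_numpy(dtype=float)
    r_all = profile.ref_count
    mask = profile.mask & (x_all + r_all > 0)

    # rescale phi to this sample's total depth: same per-exon capture factors
    # cancel, leaving T / (T + R)
    t_total = x_all[mask].sum()
    r_total = r_all[mask].sum()
    if r_total <= 0:
        return []
    phi_all = np.full(len(x_all), t_total / (t_total + r_total))

    targets = counts.targets
    idx_all = np.arange(len(targets))
    calls: list[CnvCall] = []
    chroms: list[str] = []
    for t in targets:
        if t.chrom not in chroms:
            chroms.append(t.chrom)
    for chrom in chroms:
        sel = np.array([t.chrom == chrom for t in targets]) & mask
        idx = idx_all[sel]
        if idx.size == 0:
            continue
        x, r, phi = x_all[idx], r_all[idx], phi_all[idx]
        emissions = np.column_stack(
            [emission_loglik(x, r, phi, profile.rho, c) for c in _STATE_COPY]
        )
        path = viterbi_path(emissions, transition_prob)
        for seg_start, seg_end in _nondiploid_runs(path):
            seg = slice(seg_start, seg_end)
            state = int(path[seg_start])
            copy = _STATE_COPY[state]
            cnv_type = "deletion" if copy == 1 else "duplication"
            bf = compute_bayes_factor(x[seg], r[seg], phi[seg], profile.rho, copy)
            ratio = compute_reads_ratio(x[seg], r[seg], phi[seg])
            if cnv_type == "deletion":
                copy_state = 0 if ratio < hom_ratio_threshold else 1
            else:
                copy_state = 3
            first, last = targets[idx[seg_start]], targets[idx[seg_end - 1]]
            calls.append(
                CnvCall(
                    sample_id=test_sample,
                    chrom=chrom,
                    start=first.start,
                    end=last.end,
                    type=cnv_type,
                    copy_state=copy_state,
                    bayes_factor=bf,
                    reads_ratio=ratio,
                    exon_annotation=gene_exon_annotation(
                        chrom, first.start, last.end, targets
                    ),
                )
            )
    return calls


def _nondiploid_runs(path: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(path)
    while i < n:
        if path[i] == _DIPLOID:
            i += 1
            continue
        j = i
        while j < n and path[j] == path[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


# ---------------------------------------------------------------------------
# Segment statistics
# ---------------------------------------------------------------------------

def compute_bayes_factor(
    x: np.ndarray, r: np.ndarray, phi: np.ndarray, rho: float, called_state: int
) -> float:
    """log10 likelihood ratio of the called copy state over the diploid null,
    summed over the segment's exons."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("segment must contain at least one exon")
    ll_alt = np.sum(emission_loglik(x, r, phi, rho, called_state))
    ll_null = np.sum(emission_loglik(x, r, phi, rho, 2))
    return float((ll_alt - ll_null) / math.log(10.0))


def compute_reads_ratio(x: np.ndarray, r: np.ndarray, phi: np.ndarray) -> float:
    """Observed over expected segment reads: sum(x) / sum(phi * (x + r))."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    expected = float(np.sum(phi * (x + r)))
    if expected <= 0:
        raise ValueError("expected segment read count is zero (masked exons?)")
    return float(np.sum(x) / expected)
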