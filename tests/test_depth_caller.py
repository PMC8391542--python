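"""Caller checks against independent oracles: a numerically integrated
beta-binomial mass function and exhaustive path enumeration."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from cscnv.depth_caller import (
    build_reference,
    call_cnvs,
    call_genes,
    compute_bayes_factor,
    compute_reads_ratio,
    emission_loglik,
    gene_exon_annotation,
    shifted_phi,
    viterbi_path,
    _log_transition_matrix,
)
from cscnv.synthetic_cohort import (
    CohortSpec,
    ExonTarget,
    TruthCnv,
    generate_pedigrees,
    simulate_read_counts,
)

from conftest import make_matrix


def betabinom_pmf_by_integration(x: int, n: int, p: float, rho: float) -> float:
    """Independent beta-binomial mass: integrate Binom(x|n,q) over Beta(q|a,b)."""
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    beta_norm = math.exp(
        math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    )

    def integrand(q):
        return comb(n, x) * q**x * (1 - q) ** (n - x) * q ** (a - 1) * (1 - q) ** (
            b - 1
        ) / beta_norm

    value, _ = quad(integrand, 0.0, 1.0, limit=200)
    return value


# ---------------------------------------------------------------------------
# Reference profile
# ---------------------------------------------------------------------------

def one_gene_targets(n_exons=3, length=100):
    return [
        ExonTarget("1", 1000 + i * 1000, 1000 + i * 1000 + length, "GENE", i + 1)
        for i in range(n_exons)
    ]


def test_build_reference_single_sample_counts():
    targets = one_gene_targets()
    counts = make_matrix(targets, {"R1": [10, 20, 30], "T1": [12, 18, 33]})
    profile = build_reference(counts, ["R1"])
    assert list(profile.ref_count) == [10, 20, 30]


def test_build_reference_duplicate_sample_doubles_pool():
    targets = one_gene_targets()
    counts = make_matrix(
        targets, {"R1": [10, 20, 30], "R2": [10, 20, 30], "T1": [12, 18, 33]}
    )
    single = build_reference(make_matrix(targets, {"R1": [10, 20, 30],
                                                   "T1": [12, 18, 33]}), ["R1"])
    double = build_reference(counts, ["R1", "R2"])
    assert list(double.ref_count) == [20, 40, 60]
    # the per-exon phi profile stays flat in both cases
    assert np.allclose(single.phi, single.phi[0])
    assert np.allclose(double.phi, double.phi[0])


def test_build_reference_unknown_sample_errors():
    counts = make_matrix(one_gene_targets(), {"R1": [1, 2, 3]})
    with pytest.raises(KeyError, match="NOPE"):
        build_reference(counts, ["NOPE"])


def test_build_reference_masks_zero_coverage_exons():
    counts = make_matrix(one_gene_targets(), {"R1": [10, 0, 30], "T1": [9, 1, 28]})
    profile = build_reference(counts, ["R1"])
    assert list(profile.mask) == [True, False, True]


def test_reference_phi_matches_depth_fraction(het_deletion_cohort):
    """phi ~ total test reads / (total test + total reference reads)."""
    counts, refs, _, _ = het_deletion_cohort
    profile = build_reference(counts, refs)
    tests = [s for s in counts.sample_ids if s not in refs]
    t = counts.counts[tests].to_numpy(float).sum(axis=0).mean()
    r = profile.ref_count.sum()
    assert profile.phi[0] == pytest.approx(t / (t + r), rel=1e-9)
    # one test vs four equal-depth references: about 1/5 of combined reads
    assert 0.15 < profile.phi[0] < 0.25


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi", np.linspace(0.05, 0.95, 10))
def test_diploid_leaves_phi_unchanged(phi):
    assert shifted_phi(phi, 2) == pytest.approx(phi)


def test_het_deletion_shifts_phi_by_algebra():
    assert shifted_phi(0.5, 1) == pytest.approx(1.0 / 3.0)


@pytest.mark.parametrize("copy_state", [1, 2])
def test_emission_matches_integration_oracle(copy_state):
    x, r, phi, rho = 12, 88, 0.1, 0.01
    p = float(shifted_phi(phi, copy_state))
    expected = betabinom_pmf_by_integration(x, x + r, p, rho)
    got = emission_loglik(x, r, phi, rho, copy_state)
    assert got == pytest.approx(math.log(expected), rel=1e-6)


def test_emission_finite_for_homozygous_state_with_reads():
    ll = emission_loglik(5, 400, 0.2, 0.01, 0)
    assert np.isfinite(ll)


def test_emission_rejects_double_zero():
    with pytest.raises(ValueError):
        emission_loglik(0, 0, 0.2, 0.01, 2)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def exhaustive_best_path(emissions: np.ndarray, transition_prob: float) -> float:
    log_t = _log_transition_matrix(transition_prob)
    init = log_t[1]
    best = -np.inf
    for path in itertools.product(range(3), repeat=emissions.shape[0]):
        score = init[path[0]] + emissions[0, path[0]]
        for i in range(1, len(path)):
            score += log_t[path[i - 1], path[i]] + emissions[i, path[i]]
        best = max(best, score)
    return best


def path_score(path: np.ndarray, emissions: np.ndarray, transition_prob: float) -> float:
    log_t = _log_transition_matrix(transition_prob)
    score = log_t[1][path[0]] + emissions[0, path[0]]
    for i in range(1, len(path)):
        score += log_t[path[i - 1], path[i]] + emissions[i, path[i]]
    return score


@pytest.mark.parametrize("n_exons", range(1, 9))
def test_viterbi_equals_exhaustive_enumeration(n_exons):
    rng = np.random.default_rng(n_exons)
    for _ in range(5):
        emissions = rng.normal(scale=3.0, size=(n_exons, 3))
        decoded = viterbi_path(emissions, 1e-3)
        assert path_score(decoded, emissions, 1e-3) == pytest.approx(
            exhaustive_best_path(emissions, 1e-3)
        )


# ---------------------------------------------------------------------------
# Segment statistics
# ---------------------------------------------------------------------------

def test_bayes_factor_zero_when_called_state_is_diploid():
    x, r, phi = np.array([50.0]), np.array([450.0]), np.array([0.1])
    assert compute_bayes_factor(x, r, phi, 0.01, 2) == pytest.approx(0.0)


def test_bayes_factor_matches_direct_products():
    x = np.array([12.0, 9.0, 15.0])
    r = np.array([88.0, 91.0, 85.0])
    phi = np.full(3, 0.15)
    rho = 0.01
    alt = 1.0
    null = 1.0
    for xi, ri in zip(x, r):
        alt *= betabinom_pmf_by_integration(
            int(xi), int(xi + ri), float(shifted_phi(0.15, 1)), rho
        )
        null *= betabinom_pmf_by_integration(int(xi), int(xi + ri), 0.15, rho)
    assert compute_bayes_factor(x, r, phi, rho, 1) == pytest.approx(
        math.log10(alt / null), rel=1e-6
    )


def test_bayes_factor_additive_over_exons():
    rng = np.random.default_rng(0)
    x = rng.integers(5, 40, size=6).astype(float)
    r = rng.integers(80, 120, size=6).astype(float)
    phi = np.full(6, 0.2)
    total = compute_bayes_factor(x, r, phi, 0.01, 1)
    per_exon = sum(
        compute_bayes_factor(x[i : i + 1], r[i : i + 1], phi[i : i + 1], 0.01, 1)
        for i in range(6)
    )
    assert total == pytest.approx(per_exon)


def test_reads_ratio_identities():
    phi = np.array([0.2, 0.2])
    r = np.array([80.0, 80.0])
    x = phi * r / (1 - phi)  # solves x = phi*(x+r)
    assert compute_reads_ratio(x, r, phi) == pytest.approx(1.0)
    assert compute_reads_ratio(np.zeros(2), r, phi) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        compute_reads_ratio(np.zeros(1), np.zeros(1), np.array([0.2]))


# ---------------------------------------------------------------------------
# Calling end to end
# ---------------------------------------------------------------------------

def test_no_calls_on_expectation_counts():
    targets = one_gene_targets(6)
    flat = [100, 100, 100, 100, 100, 100]
    counts = make_matrix(
        targets, {"R1": flat, "R2": flat, "R3": flat, "R4": flat, "T1": flat}
    )
    profile = build_reference(counts, ["R1", "R2", "R3", "R4"])
    assert call_cnvs("T1", counts, profile) == []


def test_homozygous_deletion_called_with_zero_ratio(small_targets, quintet):
    spec, ped = quintet
    patient = next(p for p in ped if p.affected)
    seg = [t for t in small_targets if t.gene == "G0007"][:2]
    truth = [TruthCnv(patient.sample_id, seg[0].chrom, seg[0].start, seg[-1].end,
                      "deletion", 0, "de_novo")]
    counts = simulate_read_counts(ped, small_targets, truth, spec)
    refs = [p.sample_id for p in ped if not p.affected]
    profile = build_reference(counts, refs)
    calls = [
        c for c in call_cnvs(patient.sample_id, counts, profile)
        if c.chrom == seg[0].chrom and c.start < seg[-1].end and seg[0].start < c.end
    ]
    assert len(calls) == 1
    call = calls[0]
    assert call.type == "deletion" and call.copy_state == 0
    assert call.reads_ratio == 0.0
    assert "G0007" in call_genes(call)


def test_homozygous_deletion_with_leakage_stays_below_threshold(small_targets, quintet):
    spec, ped = quintet
    leaky = CohortSpec(1, 0, 0, 0, 0, mean_depth=100, depth_dispersion=0.01,
                       leakage=0.02, seed=spec.seed)
    patient = next(p for p in ped if p.affected)
    seg = [t for t in small_targets if t.gene == "G0007"][:3]
    truth = [TruthCnv(patient.sample_id, seg[0].chrom, seg[0].start, seg[-1].end,
                      "deletion", 0, "de_novo")]
    counts = simulate_read_counts(ped, small_targets, truth, leaky)
    profile = build_reference(counts, [p.sample_id for p in ped if not p.affected])
    calls = [
        c for c in call_cnvs(patient.sample_id, counts, profile)
        if c.chrom == seg[0].chrom and c.start < seg[-1].end and seg[0].start < c.end
    ]
    assert calls and calls[0].reads_ratio < 0.1
    assert calls[0].copy_state == 0


def test_het_deletion_recovery_rate(small_targets):
    """>=90% of seeded replicates recover an implanted 3-exon het deletion
    with BF > 1 and reads ratio in [0.35, 0.65]."""
    seg = [t for t in small_targets if t.gene == "G0005"][:3]
    hits = 0
    n_rep = 200
    for s in range(n_rep):
        spec = CohortSpec(1, 0, 0, 0, 0, mean_depth=100, depth_dispersion=0.01,
                          seed=1000 + s)
        ped = generate_pedigrees(spec)
        patient = next(p for p in ped if p.affected)
        truth = [TruthCnv(patient.sample_id, seg[0].chrom, seg[0].start,
                          seg[-1].end, "deletion", 1, "de_novo")]
        counts = simulate_read_counts(ped, small_targets, truth, spec)
        profile = build_reference(counts, [p.sample_id for p in ped if not p.affected])
        calls = call_cnvs(patient.sample_id, counts, profile)
        hits += any(
            c.type == "deletion"
            and c.chrom == seg[0].chrom
            and c.start < seg[-1].end
            and seg[0].start < c.end
            and c.bayes_factor > 1
            and 0.35 <= c.reads_ratio <= 0.65
            for c in calls
        )
    assert hits / n_rep >= 0.9


def test_specificity_on_cnv_free_cohort():
    """On CNV-free counts, confident calls stay below 5 per 1000 exons."""
    from cscnv.synthetic_cohort import generate_exon_targets

    targets = generate_exon_targets(200, (4, 8), (100, 200), (500, 2000), seed=6)
    spec = CohortSpec(1, 0, 1, 0, 0, mean_depth=100, depth_dispersion=0.01, seed=77)
    ped = generate_pedigrees(spec)
    counts = simulate_read_counts(ped, targets, [], spec)
    refs = [p.sample_id for p in ped if not p.affected][:4]
    tests = [p.sample_id for p in ped if p.sample_id not in refs]
    profile = build_reference(counts, refs)
    n_exons = len(targets)
    for sample in tests:
        confident = [
            c for c in call_cnvs(sample, counts, profile) if c.bayes_factor > 1
        ]
        assert len(confident) / n_exons * 1000 < 5


def test_annotation_formats():
    targets = [
        ExonTarget("1", 100, 200, "A", 1),
        ExonTarget("1", 300, 400, "A", 2),
        ExonTarget("1", 1000, 1100, "B", 1),
    ]
    assert gene_exon_annotation("1", 50, 450, targets) == "A_1-2"
    assert gene_exon_annotation("1", 310, 350, targets) == "A_2"
    assert gene_exon_annotation("1", 500, 900, targets) == ""
    assert gene_exon_annotation("1", 150, 1050, targets) == "A_1-2,B_1"
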