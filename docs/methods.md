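# Methods

## Read-depth model

Calling is conditional: given the total `n = x + r` of test-sample and pooled
reference counts at an exon, the test count follows a beta-binomial whose
success fraction depends on the test sample's copy number `c`:

    phi'(c) = (c/2)·phi / ((c/2)·phi + (1 − phi)),

so the diploid state leaves `phi` unchanged, a heterozygous deletion roughly
halves the test sample's share of reads, and a single-copy gain raises it by
half. Conditioning on `n` removes the shared per-exon capture efficiency and
total-depth effects, which is why a single `phi` per sample suffices.

**phi.** Because expected test and reference counts at an exon scale with the
same capture factor, the expected test fraction reduces to `T / (T + R)` with
`T` the test sample's total on-target reads and `R` the pooled reference
total. `build_reference` stores the value for a typical (mean-depth)
non-reference sample; `call_cnvs` rescales it to each test sample's own total
before decoding. With four reference samples of comparable depth this sits
near 1/5.

**rho.** The overdispersion (beta-binomial intra-class correlation) is fitted
by the method of moments on leave-one-out reference-vs-rest splits: the mean
standardized squared residual of `x` against Binomial(n, p) exceeds 1 by
`(mean(n) − 1)·rho`. The estimate is floored at 1e-4; a single-sample
reference pool falls back to the floor. This keeps the emission honest about
the extra-binomial noise of capture without per-exon parameters.

**Homozygous losses.** An emission at `c = 0` would put zero mass on any
observed read, yet homozygously deleted loci do show stray (mis-mapped)
reads. The emission therefore substitutes an effective copy number of 0.02,
and homozygous vs heterozygous deletion is decided after segmentation from
the segment's observed/expected ratio against the 0.1 discriminator — the
same threshold the recessive screen uses. Exons whose pooled reference count
is zero are masked out of decoding entirely (a warning is logged).

## Segmentation

Hidden states {deletion, diploid, duplication} form a first-order chain over
the position-ordered exons of each chromosome. Leaving the diploid state
costs `transition_prob` (default 1e-4) per alternative state, so staying
diploid has probability 1 − 2·1e-4 per boundary. Non-diploid states persist
with probability 0.7 and otherwise return to diploid (direct del↔dup hops
get the same 1e-4). The asymmetry is deliberate: a CNV should be penalized
once, on entry, at a strength matching its genome-wide rarity, while closing
a segment must stay cheap — with a symmetric matrix the exit penalty doubles
the evidence a short event needs, and measured recovery of 3-exon
heterozygous deletions dropped from ~94% to ~60%. The chain starts as if
preceded by a diploid exon. Decoding is exact Viterbi; tests verify it
against exhaustive enumeration over all `3^n` paths for up to 8 exons.

Per decoded segment, the Bayes factor is the base-10 log likelihood ratio of
the called state over diploid summed over exons (additive by construction,
and it can be negative), and the reads ratio is `Σ x_i / Σ phi_i (x_i + r_i)`.

## Filter cascade

Only stated exclusion rules are applied, so boundary values survive: BF
exactly 1, size exactly 100 bp and frequency exactly 0.01 are all kept.
Population-frequency filtering is gene-based — overlapping CNVs lack crisp
boundaries — taking the maximum heterozygous-loss frequency over all
eligible records of both databases, with East-Asian values participating
whenever present and records from surveys of fewer than 100 samples ignored;
genes without any eligible record are retained. A call annotated to several
genes survives if any of its genes does, since downstream stages are
themselves gene-scoped. The 100-bp size filter runs only on the genome-wide
path: the candidate-gene screen deliberately bypasses it so that short
single-exon hits in known scoliosis genes (e.g. a 71-bp first-exon deletion)
are not discarded by a rule meant to curb genome-wide noise.

## Inheritance and recessive calls

Parental carriage is judged on each parent's own call set (per-sample
calling, no joint genotyping): a parent carries the variant if it has a call
of the same type sharing an annotated gene (default) or reciprocally
overlapping ≥ 50% (interval mode). Gene-level is the default because
independently called inherited events often differ in exact boundaries.
Both parents assayed and clean → de novo; exactly one carrier → paternal /
maternal; both → biparental; any parent missing → not determined. Sibling
absence is recorded as an annotation (starred in reports) and never required
for the de novo label. Homozygous calls are deletions with ratio < 0.1
(strict); the recessive report keeps those whose gene is never homozygous in
any control.

## Recurrence enrichment

Discovery runs on patients from complete families (both parents assayed:
quintets, quartets, trios); counts are then updated with the remaining
patients. A gene is reported when it has at least 4 patient carriers ("more
than three"), its control-carrier fraction is below 1% (with 125 controls
this admits 0 or 1 carriers; 2/125 = 1.6% fails), and its maximum eligible
population frequency is ≤ 0.01. Distinct-CNV counting keys on
(chromosome, start, end, type) — sample identity and scores are irrelevant
to "the same CNV recurring".

## Synthetic cohorts

The generator emulates the study conditions: 2 quintets, 14 quartets, 33
trios, 9 duos and 9 singletons (67 affected, 125 unaffected; one affected
child per family, parents before siblings, duos keeping the mother), exon
targets laid out over autosomes, and negative-binomial exon counts with
expected value `mean_depth · (c/2) · length/mean_length` and variance
`mu + d·mu²` (d → 0 recovers Poisson; defaults 100× and d = 0.01). A
`leakage` parameter (default 0) leaves residual coverage at homozygous
deletions so near-zero ratios like 0.04 can be exercised. Implanted events
span whole exons in distinct genes; heterozygous events may be inherited
(also planted in one parent), homozygous ones are de novo and
patient-restricted. Companion frequency tables make implanted genes rare
(< 0.01), give a configurable share of background genes common frequencies,
and include under-powered records that filters must ignore.

Not modeled: GC and batch effects, alignment artifacts, sex chromosomes,
mosaicism, multiplex families, and the per-sample optimized reference-set
selection of production callers (the reference list is fixed configuration).
Passing tests therefore demonstrate the statistical machinery under clean
capture noise, not robustness to real-data systematics.

## Reconstructed study tables

`studytables` re-encodes the published candidate, recessive and recurrence
tables as in-memory fixtures, with printed coordinates, Bayes factors,
ratios, annotations and frequencies kept verbatim (0-based half-open
intervals, so every printed size equals end − start). Quantities the study
does not print are synthetic and marked as such: filler family identities,
carrier assignments and coordinates for the recurrence genes, decoy genes
that each violate exactly one prioritization rule, a second control DSCAM
carrier (required for the gene's absence from the recurrence table), and all
qPCR cycle thresholds. Genes of the 16p11.2 region co-annotated on the TBX6
calls receive a common (0.05) frequency so only TBX6 itself survives the
frequency rule there.

## Problem sizes and statistical checks

Caller tests use 20-gene target sets (4–8 exons each) with quintet cohorts
at 100× depth; specificity uses a CNV-free 200-gene (~1200-exon) cohort.
The heterozygous-deletion recovery property is measured over 200 seeded
replicates: the underlying recovery rate is ~94%, so 200 replicates keep the
≥ 90% assertion's false-failure probability below 0.5%, whereas batches of
50 would fail by binomial noise alone several percent of the time. The
de novo classification check runs on 20 perfect-call trios and demands exact
agreement. All generators are deterministic given their seed; identical
configuration reproduces byte-identical pipeline outputs.

## Known limitations

Duplications are genotyped only as copy 3; the caller does not use split-read
or paired-end evidence; "allele frequency" for duplications reuses the
heterozygous-loss frequency fields, mirroring how the recurrence table lists
a duplication under a loss-frequency column; and the enrichment screen
performs no significance testing, as the underlying workflow defines none.
The reconstructed tables surface two internal inconsistencies of the source
counts (an abstract total of 15 genes vs 14 in the table it summarizes, and
63 vs 64 summed recurrent CNVs); the reports always state their own computed
counts.
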