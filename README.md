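# cscnv

Exon read-depth CNV calling and family-based prioritization for congenital
scoliosis (CS) cohorts.

Congenital scoliosis is a lateral spinal curvature caused by congenital
vertebral malformations, most often hemivertebrae. Beyond the established
*TBX6*-containing 16p11.2 microdeletion, rare copy-number variants (CNVs) are
suspected contributors, and cohort studies look for them in whole-exome
sequencing (WES) of affected children and their unaffected relatives. This
package implements that analysis end to end for methodologists and
genetic-epidemiology students: a synthetic cohort generator (family-structured
exon read counts with implanted CNVs), a read-depth caller, the rare-CNV
filter cascade, trio-based inheritance classification, recessive-CNV
detection, candidate-gene and recurrence-enrichment screens, and a qPCR
copy-number calculator.

## The model

For a test sample with count `x` at an exon where the pooled reference set of
control samples has count `r`, calling works on the conditional distribution

```
x | (x + r)  ~  BetaBinomial(n = x + r, phi'(c), rho)
phi'(c) = (c/2)·phi / ((c/2)·phi + (1 − phi))
```

where `phi` is the expected fraction of test reads among test + reference
reads under the diploid state (`c = 2` gives `phi' = phi`), `c` is the copy
number, and `rho` is the overdispersion fitted from reference-vs-reference
splits. A three-state chain (deletion / diploid / duplication) over the
ordered exons of each chromosome is decoded by the Viterbi maximum-probability
path; maximal non-diploid runs become calls. Each call carries

* a **Bayes factor**, `BF = log10 Π L(x_i | c_called) / Π L(x_i | c = 2)`, and
* an **observed/expected reads ratio**, `Σ x_i / Σ phi_i (x_i + r_i)`
  (≈ 0.5 for a heterozygous loss, < 0.1 for a homozygous loss, ≈ 1.5 for a
  single-copy gain).

Downstream filters follow the study workflow: exclude calls with BF < 1,
size < 100 bp (genome-wide path only), or a gene whose maximum eligible
population heterozygous-loss frequency (DGV-like / gnomAD-like records with
survey size ≥ 100) exceeds 0.01; classify inheritance against assayed
parents; report homozygous CNVs (ratio < 0.1) unique to patients; and report
genes recurrently hit in > 3 patients but < 1% of family controls. qPCR
validation uses `2^−ΔΔCt` with a reference locus and a diploid calibrator.

## Worked example

Simulate a small cohort (1 quartet + 3 trios, mean exon depth 100×, six
implanted de novo heterozygous CNVs), call, filter and classify:

```
$ cscnv simulate --config sim.yaml --out-dir data
$ cscnv call --counts data/counts.tsv --targets data/targets.bed \
      --reference-samples F001Q4F,F001Q4M,F001Q4S1,F002T3F --out calls.tsv
6 calls written to calls.tsv
$ cscnv filter --calls calls.tsv --popfreq data/popfreq.tsv --out calls_f.tsv
6 calls survive
$ cscnv inherit --calls calls_f.tsv --ped data/cohort.ped --out inh.tsv
6 patient calls annotated
$ head -3 inh.tsv | cut -f1-3,6,8-10
sample_id  type         chrom  size_bp  reads_ratio  exon_annotation  inheritance
F001Q4P    deletion     18     26266    0.558        G0018_11-20      De novo
F003T3P    duplication  15     16027    1.361        G0015_2-8        De novo
```

All six implanted events are recovered: the deletion shows the expected
half-coverage ratio (0.558 ≈ 0.5), the duplication the expected 3/2 gain
(1.361 ≈ 1.5), and with both parents assayed and clean, each classifies as
"De novo". The ΔΔCt calculator converts qPCR cycle thresholds to copies:

```
$ cscnv qpcr --ct-table ct.tsv --calibrator CAL --out q.tsv
sample_id target_locus  delta_ct  delta_delta_ct  relative_quantity  copy_estimate
      CAL           G1       0.0             0.0                1.0            2.0
       S1           G1       1.0             1.0                0.5            1.0
```

A sample running one cycle late at the target locus (ΔΔCt = 1) has half the
relative quantity — one remaining copy, a heterozygous deletion.

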