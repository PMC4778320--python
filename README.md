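# isoswitch

Genome-wide detection of mRNA **isoform switching** in bulk RNA-seq cohorts.

Most genes express a predominant transcript whose abundance tracks the other
isoforms of the gene and the gene total. The interesting exceptions are
*switching* pairs: a predominant and an alternative isoform whose usage is
inversely correlated across samples — sometimes with no change in total gene
expression at all, so ordinary differential-expression analysis never sees
them. Two forces generate such inverse patterns in real cohorts: biology
(subtype-linked or subpopulation-linked splicing programs) and artifact
(partial RNA degradation inflates short transcripts under polyA-primed
protocols, mimicking a switch). This package implements the full screen that
separates them, for analysts working with isoform-level quantifications
(RSEM-style expected counts) and per-sample RNA Integrity Numbers (RIN).

## The analysis

Per sample, abundances are upper-quartile normalized and log2 transformed;
a transcript is **detected** if it has ≥ 3 normalized counts in > 60% of
samples. For each gene the **predominant isoform** maximizes the
upper-quartile abundance across samples, and each other detected isoform
forms a candidate pair. The pipeline then runs:

1. **First-pass screen** — OLS of alternative on predominant (log2);
   keep pairs with a significantly negative slope.
2. **Degradation screen** — hierarchical clustering of samples on the
   passing pairs' isoforms; if the 2-cut separates a low-RIN cluster,
   pairs whose members are differentially expressed between the clusters in
   opposite directions are flagged as RNA-degradation artifacts (the high
   member is typically the shorter transcript).
3. **RIN-adjusted switch model** — per pair,
   `y_alt ~ β0 + β1·RIN + β2·x_pred`; a **switch** requires β2 < 0 with
   p(β2) < 0.05 while p(β1) > 0.2, so degradation-explained pairs drop out.
4. **Subtype association** — Welch t-tests of the per-sample usage ratio
   `log2(alt+1) − log2(pred+1)` for each intrinsic subtype one-vs-rest
   (plus Basal vs luminal), with a parallel test on total gene abundance to
   find switches invisible at the gene level.
5. **Bimodal screen** — subtype-independent switches are K-means-clustered
   (k = 2) on the pair's two abundances; a pass needs two clusters of > 50
   samples, both isoforms expressed in both clusters, and inverted usage.
6. **Quantitative SAM** — genes whose expression tracks a chosen pair's
   usage ratio, ranked by the moderated statistic d = r/(s + s0) with a
   permutation FDR; selected genes are grouped into four signatures by
   hierarchical clustering.

A synthetic-cohort generator (`isoswitch.simulate`) plants all four event
classes — degradation artifacts, subtype switches, bimodal switches, and a
ratio-supervised gene signature — with a ground-truth registry, so the whole
pipeline is exercised and scored without any external download. Model
details, parameter choices and limitations: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
reference cohort (300 samples, 2000 genes, seeded):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_detect_and_describe.py
python analysis/03_switch_screens.py
python analysis/04_subtype_association.py
python analysis/05_bimodal_screen.py
python analysis/06_sam_signature.py
```

Output of the switch-screen step on the reference cohort:

```
1924 predominant/alternative pairs; 87 pass the first-pass inverse-correlation screen
RIN screen: clusters of {2: 260, 1: 40} samples, RIN difference p = 2.75e-35
  30 artifact pairs flagged (30 with the shorter isoform high in the low-RIN cluster);
  30/30 planted artifacts recovered
RIN-adjusted model: 42 switch pairs from 42 genes
  planted subtype switches recovered: 36/50; bimodal: 6/10; false discoveries: 0
```

Reading: of 1924 candidate pairs, 87 are significantly inversely correlated;
clustering isolates a 40-sample low-RIN stratum and attributes 30 pairs to
degradation, every one with the short isoform elevated in degraded samples.
After RIN adjustment, 42 pairs remain as switches with zero false
discoveries; recovered subtype switches sit near the ≈ 80% ceiling imposed
by the RIN non-significance criterion (a true switch has a uniform RIN
p-value, which exceeds 0.2 with probability 0.8). The SAM step then recovers
all 300 planted signature genes at empirical FDR ≈ 0.04:

```
SAM (s0 = 0.0084 at the 0th percentile of s): 313 genes selected at FDR <= 0.05
planted signature genes recovered: 300/300; empirical FDR 0.042
```

The same stages are available as a library (`isoswitch.*`), as one call
(`isoswitch.run_all(config, out_dir)` with a YAML/dict config), and as a
console script (`isoswitch simulate`, `isoswitch run`).

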