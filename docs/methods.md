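# Methods

`isoswitch` implements a genome-wide screen for mRNA isoform switching in
bulk RNA-seq cohorts: starting from an isoform × sample abundance matrix, it
identifies predominant/alternative transcript pairs whose usage is inversely
correlated, separates degradation artifacts from biology using RNA Integrity
Numbers (RIN), classifies the surviving switches by tumor subtype, screens
the subtype-independent remainder for genuine bimodal subpopulations, and
derives gene-expression signatures supervised by an isoform-usage ratio.
This note records the model, the tunable parameters, the numerical choices,
and what the synthetic cohort does and does not establish.

## Normalization and detection

Each sample is scaled so that the 75th percentile of its strictly positive
abundances equals a fixed target (default 1000). Zeros are excluded from the
quantile: a large fraction of annotated transcripts is unexpressed in any
one cohort, and including them would frequently drive the upper quartile to
zero. Quantiles use linear interpolation between order statistics (the
convention with index h = (n−1)p + 1, numpy's default); a fixed convention
is needed for exact reproducibility, and this is the one used throughout
(normalization, predominant-isoform selection, SAM's s0 grid).

Log transformation is `log2(x + 1)`; the unit offset maps 0 to 0 and leaves
well-expressed transcripts essentially on the log2 scale.

A transcript is *detected* when its normalized abundance is at least
`min_count` (default 3) in strictly more than `min_fraction` (default 0.60)
of samples. The boundary is exclusive: presence in exactly 60% of samples
does not qualify. All downstream stages operate on detected transcripts.

Gene-level abundance, needed for the subtype gene-expression test and for
SAM, is the sum of the gene's isoform abundances on the normalized scale,
then log2 with the same offset — the convention under which RSEM-style gene
counts decompose into isoform counts.

## Switch detection

For each gene the *predominant* isoform is the detected transcript with the
greatest upper-quartile abundance across all samples (ties: greater total
abundance, then lexicographically smaller identifier). Every other detected
isoform of the gene forms a candidate (predominant, alternative) pair.

**First pass.** Ordinary least squares of the alternative on the predominant
isoform (both log2) with intercept; a pair passes when the slope is negative
with a two-sided t-test p below 0.05. OLS is implemented from the normal
equations; the test suite verifies coefficients, standard errors, and
p-values against statsmodels to 1e−10.

**Degradation screen.** Partial RNA degradation under polyA-primed library
preparation inflates the apparent abundance of shorter transcripts, which
mimics switching. Samples are clustered on the isoforms of all first-pass
pairs: rows are mean-centered, the distance between sample profiles is
1 − Pearson correlation, linkage is agglomerative average, and the tree is
cut into two clusters. A Welch t-test on RIN labels the low-RIN cluster;
per-isoform Welch tests between the clusters (Benjamini–Hochberg corrected
at 0.05) assign each isoform a direction, and a pair whose members move in
opposite directions is flagged as a degradation artifact. Mean-centering
(rather than the older median-polish convention, which remains available via
`center="median"`) is the default because it keeps the *majority* stratum
coherently offset opposite to a minority of degraded samples, letting the
correlation distance isolate the degradation stratum even when large
subtype blocks are present among the features; with median-centering the
intact majority sits exactly at zero and the degraded-versus-intact
bipartition can lose the final dendrogram merge to the largest subtype
block. Flagged pairs are reported, not removed: the exclusion mechanism is
the adjusted model below.

**RIN-adjusted model.** Per pair, OLS of the alternative isoform on RIN and
the predominant isoform (with intercept), over all samples, tumor and normal
alike:

    y_alt ~ β0 + β1·RIN + β2·x_pred

A pair is called a switch iff β2 < 0, the p-value for the predominant
coefficient is below 0.05, and the p-value for the RIN coefficient *exceeds*
0.2 (strictly; boundary equality fails). The last criterion rejects pairs
whose inverse correlation is explained by degradation. Its statistical cost
is intrinsic: for a genuine switch with no RIN dependence the RIN p-value is
uniform, so the criterion passes true switches with probability ≈ 0.8 — a
sensitivity ceiling that no effect size or sample size lifts. The planted-
event evaluation on the reference cohort measures sensitivity ≈ 0.72–0.86
accordingly, with a false-discovery proportion at or near zero.

Welch (unequal-variance) t-tests are used wherever two groups are compared;
group sizes in subtype contrasts are very uneven and the pooled-variance
test would be anticonservative for the small groups.

## Subtype association

The expression pattern of a pair is summarized per sample by the usage
ratio `log2(alt + 1) − log2(pred + 1)` on the normalized scale — a bounded,
antisymmetric statistic that is insensitive to gene-level expression
changes. Each intrinsic subtype (Basal, Her2, LumA, LumB, Normal-like) is
contrasted one-vs-rest among tumor samples with a subtype call; a sixth
contrast compares Basal against LumA ∪ LumB. Significance is a Welch t-test
at p < 0.05 with no multiplicity correction, matching the screening
character of this stage (an FDR mode is available in the per-test alpha).
The same test applied to log2 gene abundance records whether total
expression differs; switches with constant gene level are the cases where
splicing carries information invisible to gene-level analysis. A pair may
be associated with several contrasts; the summary table counts pairs,
distinct genes, and gene-level-constant pairs per contrast.

Adjacent-normal tissue carries no subtype call (`NA`) and is excluded from
subtype contrasts but retained in the switching regressions, which use all
samples.

## Bimodal screen for subtype-independent switches

Switch pairs with no one-vs-rest association may reflect two genuine sample
subpopulations — or a rare event in a handful of samples. K-means with k=2
(10 restarts, seeded) on the pair's two log2 abundances splits the cohort;
the pair passes when (i) both clusters hold strictly more than 50 samples,
(ii) each isoform's within-cluster median abundance reaches the detection
threshold in both clusters, and (iii) the cluster mean differences of the
two isoforms have opposite signs (inverted usage). Cluster 1 is defined as
the cluster with the higher mean of the first member, making labels stable
under sample permutation. A Welch t-test on RIN between the clusters is
reported so that degradation-driven splits are recognizable. On unimodal
null pairs the pass rate is ≈ 0 (the split of a positively correlated cloud
moves both isoforms in the same direction, failing criterion iii).

## Quantitative SAM

Genes whose expression tracks an isoform-usage ratio are found with the
quantitative variant of Significance Analysis of Microarrays. For gene i,
r_i is the least-squares slope of log2 gene abundance on the centered
response (the pair's usage ratio), s_i its standard error, and

    d_i = r_i / (s_i + s0)

with the fudge factor s0 chosen from a grid of percentiles of the s_i
distribution (0, 5, …, 100) to minimize the coefficient of variation of the
median absolute deviation of d_i across s_i-quantile bins — the standard
automatic rule; a fixed percentile can be forced. The null distribution
comes from permuting the response (default 200 permutations, seeded). For a
cut at the m-th largest |d|, the estimated FDR is the median over
permutations of the number of null |d| values beyond the cut, divided by m;
q-values take the minimum estimated FDR over all cuts containing the gene,
which makes them non-decreasing as |d| decreases. Selection at a threshold
of exactly 0 is stricter than q = 0 under the median rule: it requires that
*no* permutation yields any statistic beyond the cut (equivalently
|d| must exceed the largest null |d|), because the median of the null
exceedance counts is zero for the top gene in about half of pure-noise
datasets and a literal q = 0 selection would be uncalibrated. Reported
"FDR = 0" gene sets are therefore bounded by 1/n_permutations rather than
literally zero.

Selected genes are grouped into k = 4 signatures by agglomerative
clustering of gene rows (1 − Pearson distance, average linkage), labels
ordered by cluster size.

## The synthetic cohort

The generator (`isoswitch.simulate`) produces cohorts with the statistical
structure the analysis assumes, plus a registry of planted events, so every
stage can be scored without external data. Reference configuration
(`SimConfig()` defaults): 300 samples (11% adjacent normals; tumor subtypes
Basal 18%, Her2 8%, LumA 40%, LumB 22%, Normal-like 12%), 2000 genes with
1/2/3+ isoforms in proportions 0.43/0.24/0.33 (3+ split 0.50/0.30/0.15/0.05
over 3–6), gene log2 abundance N(6, 1.5²), isoform lengths log-uniform on
[500, 10000] nt.

Per sample, gene abundance is the gene mean plus N(0, noise_sd = 0.2) log2
noise shared by the gene's isoforms; usage proportions are a fixed Dirichlet
draw (concentration 3) per gene; each isoform value additionally receives
N(0, 0.3) log2 noise and a per-sample library-depth factor N(0, 0.3) that
upper-quartile normalization must undo. Under these defaults the median
within-gene pair correlation is ≈ 0.31 with ≈ 3% of pairs negative —
the predominantly-positive regime observed in real isoform-level cohorts.

Planted events (all disjoint by gene, all registered in the truth file):

* **Degradation artifacts** (30 genes, forced 2 isoforms): the shorter
  isoform's log2 usage share gains 0.5·(10 − RIN) per sample, renormalized.
  RIN itself is a two-stratum mixture: intact samples draw from a left-
  skewed Beta(3, 1) scaled to [7, 10], and 15% of tumors form a degraded
  stratum uniform on [2, 5.5]; normals are always intact (their RINs are
  uniformly high in the emulated setting). The discrete degraded stratum is
  what makes "a cluster of samples with low RIN" a real object for the
  screen to find; stratum membership is allocated proportionally within
  each subtype so specimen quality is independent of tumor biology.
  A continuous RIN spread at the same effect size does not produce a
  separable low-quality stratum at these event counts.
* **Subtype switches** (50 genes, 2 isoforms, assigned round-robin over the
  five subtypes): the pair's log2 usage ratio shifts by +δ/2 in the target
  subtype and −δ/2 elsewhere (δ = 2.5), applied as ±δ/4 to each member with
  shares renormalized, so the gene total is exactly conserved — switches
  with no gene-level expression change.
* **Bimodal switches** (10 genes): the same flip with δ = 3, driven by a
  per-sample latent Bernoulli(0.4) state independent of subtype.
* **Signature genes** (300 single-isoform genes): log2 abundance gains
  slope × (centered latent usage ratio of the first bimodal pair), with
  |slope| ~ N(0.5, 0.05). Slopes are signed — half the signature rises with
  the ratio and half falls — and sign assignment pairs genes matched on
  baseline expression (adjacent ranks share a magnitude with opposite
  signs). This balance is deliberate: a one-directional signature of this
  size shifts each sample's upper quartile coherently with the response,
  and normalization then imprints the response onto *every* gene — a
  composition bias that would invalidate the normalization assumption the
  analysis (and any upper-quartile-normalized cohort) rests on. Real
  signatures contain both directions; the generator makes the balance
  exact. Signature genes are single-isoform so the cancellation holds on
  the isoform scale where the quantile is computed.

Determinism: one seeded generator drives all draws; identical configuration
and seed reproduce the matrices bit-for-bit.

### What the synthetic cohort does not show

The generator is log-normal (a negative-binomial count layer is not
modeled), isoform usage is constant across samples apart from planted
flips and noise, transcripts are independent given their gene, and
degradation affects only the planted artifact genes rather than acting
transcriptome-wide with transcript-length-dependent strength. Passing the
planted-event evaluation therefore demonstrates that the pipeline's
statistics recover the structures they target at realistic effect sizes
and cohort scale — not that real cohorts meet the model's assumptions, nor
that the specific headline counts of any real study would be reproduced.

## Evaluation and problem sizes

`isoswitch.evaluation.run_reference_analysis` runs the complete pipeline on
a simulated cohort and scores each stage against the registry, matching
pairs orientation-insensitively (a strong flip can legitimately swap which
member the pipeline designates predominant; every verdict is symmetric in
the pair). `scripts/acceptance.py` reports these metrics for the reference
configuration — 300 samples × 2000 genes, ≈ 3900 transcripts, 200 SAM
permutations, a 200-pair null panel for the bimodal screen, and a
100-pair × 50-permutation label-shuffle panel for subtype-test calibration —
sizes chosen so the full evaluation completes in well under a minute on one
CPU while keeping every planted-event class at high power. The analysis
scripts under `analysis/` run the same stages narratively and write their
tables under `results/`.

## Known limitations

* The RIN non-significance criterion's ceiling means measured switch sensitivity
  concentrates near 0.8 of planted switches; this is a property of the
  published decision rule, not of the implementation.
* The degradation screen assumes the 2-cut of the sample dendrogram
  captures the quality stratum; when degradation variance is small relative
  to the strongest biological block the cut lands elsewhere, the reported
  cluster-RIN p-value is non-significant, and the artifact set should be
  read with that diagnostic in mind.
* Subtype contrasts are marginal one-vs-rest tests; a pair associated with
  several subtypes is counted in each, and no joint model across contrasts
  is attempted.
* SAM's permutation null assumes exchangeable samples under the null;
  strong confounding between the response and unmodeled batch structure
  would inflate the signature.
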