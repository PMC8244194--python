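# Methods

This note documents the models and procedures implemented in `methar`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not demonstrate.

## Methylation preprocessing

Beta values β ∈ [0, 1] are the fraction of methylated signal per CpG.
The flow is fixed: BMIQ normalization → exclusion-list filters →
detection-p filter → variable-promoter subset. Exclusion-list filters run
before the detection-p rule; order affects only the per-rule counts in
the `FilterReport`, never the final probe set, and fixing it makes
reports deterministic.

**BMIQ.** Infinium type-II chemistry compresses betas toward 0.5
relative to type-I probes. Per sample, a 3-state beta mixture
(unmethylated / hemimethylated / methylated) is fitted separately to each
probe type by EM — initialized from quantile cuts at β < 1/3 and
β > 2/3, method-of-moments M-step, relative log-likelihood tolerance
1e-4, at most 100 iterations, fully deterministic. Each type-II beta is
then quantile-mapped through F₁⁻¹(F₂(β)), the fitted type-II mixture CDF
composed with the inverse of the type-I mixture CDF (inverted on a
4001-point grid with linear interpolation; mixture CDFs are strictly
increasing on (0, 1), so the map is strictly monotone and within-sample
rank order is preserved). Type-I probes always pass through unchanged. A
sample whose EM does not converge is left unnormalized with a warning
rather than half-mapped.

A known property of this map: it restores the *marginal* type-II
distribution but restores *cross-sample* variance only through its local
slope, which for mid-range betas (β ≈ 0.5) is fitted at roughly 0.9–1.0
of the ideal decompression. CpGs whose true SD sits near a downstream SD
threshold can therefore fall on either side of it after normalization.

**Filters.** "Near SNP" is strict: distance < 5 bp removes the probe,
exactly 5 bp retains it. A probe is removed when detection p > 0.05 in
*any* sample. The promoter subset keeps probes with at least one gene
mapping in {TSS1500, TSS200, 5UTR} — probes mapping to several genes are
kept if any mapping is a promoter class, and all promoter mappings are
retained for gene-level integration — and across-sample SD (n−1
denominator, all samples pooled; "overall SD" is not defined per group)
strictly above 0.05.

## Differential methylation and integration

A DM-CpG has |mean β(group 1) − mean β(group 2)| strictly greater than
0.3. The paired T/N design is reduced to a difference of group means
(equal to the mean paired difference for complete pairs); no paired-test
variant exists because the definition is a mean delta-beta, not a test.
The three comparisons (T vs N, M vs N, M vs T) are partitioned into all
seven Venn regions; `unique_mt = MT \ (TN ∪ MN)` isolates CpGs that
diverge in metastasis only.

Integration evaluates every transcript of every promoter-mapped DM gene:
Wilcoxon rank-sum on transcript level between the groups, Pearson r
between β and transcript across the pooled samples. *hyper-down* =
hypermethylated CpG, expression down, p < 0.05, r < 0 (or r < −r_max
when a stricter threshold is requested, as in the AR analysis where 0.4
is used); *hypo-up* symmetric. Classification uses unadjusted p; BH-
adjusted values are reported alongside for transparency. Genes without
expression data are emitted as `no-data`, never dropped. A gene with
several transcripts is classified by its most significant concordant
transcript, but every transcript record is retained.

## Pathway-activity scores

A panel score is the first principal component score *t*[1] of the
mean-centered (not variance-scaled — centering matches the expression
preprocessing convention) panel submatrix, computed by SVD. Sign is fixed
by requiring a positive loading for an anchor gene: KLK3 for the AR
panel, TOP2A for the proliferation panel — canonical positive markers of
each program; without an anchor the component sign is solver-dependent.
Up to 25% of panel genes may be absent (this tolerance allows scaled-down
cohorts); the anchor must be present. Historic symbols are resolved
through a small alias table (CDC2→CDK1, ORC6L→ORC6, KIAA0101→PCLAF,
CDAN1→CDIN1) in both directions.

## The MCA classifier

Signature selection runs on normalized promoter betas of the metastases
that carry an AR score: keep CpGs with SD > 0.15 (n−1) and
|Pearson r| ≥ 0.4 (boundary inclusive) against the AR score;
zero-variance probes are excluded before the correlation, which is
otherwise undefined. Selection is invariant to sample order and to
positive affine rescaling of the scores.

Clustering uses Euclidean distance with complete linkage, cut at k = 2 —
an explicit operationalization of "default heatmap clustering settings";
both are configurable and the dendrogram is exported (Newick text). The
cluster with the higher median AR score is MCA positive; negating all
scores flips the labels but not the partition. Silhouette widths use the
standard (b − a)/max(a, b) with 0 for singleton or degenerate cases.
Samples without a transcriptome receive no score and no label.

## Copy number

Total intensity (methylated + unmethylated) is proportional to local
copy number up to sample-level scaling. Ratios are
log2((I_query + 1)/(mean reference I + 1)), median-centered per sample so
that global scaling cancels exactly (up to the O(1/intensity)
pseudocount term). The region statistic is the 10%-trimmed mean (10% per
tail) of the region's ratios, robust to single outlier probes; the call
thresholds ±0.3 replace a manual inspection step and are exposed in the
API. The region is defined by manifest gene annotation (default "AR"),
not hard-coded coordinates.

## Survival

Events are cancer-specific deaths; other deaths and administrative ends
are censored. Kaplan–Meier medians use min{t : S(t) ≤ 0.5} (undefined if
the curve never crosses 0.5). The two-group comparison is the log-rank
test — the standard companion of KM when no test is named. Cox models
use Efron tie handling (months-resolution follow-up ties often);
categorical covariates are reference-coded (MetA reference for the
metastasis subtypes). Covariates with univariate p < 0.05 — minimum over
a factor's levels — enter the multivariate model. Fewer than 10 events
triggers a warning rather than an error.

## Synthetic cohorts

The generator emulates the structure of a paired prostatectomy series
plus a metastasis series: 12 N/T pairs, 70 metastases (14 hormone-naive
/ 4 short-term castrated / 52 castration-resistant), 20,000 probes (60%
promoter), 4,000 genes, transcriptomes for all N/T and 66 of 70 M
samples. Defaults, with rationale where the choice was open:

* Probe-state means 0.10 / 0.50 / 0.85, beta-distribution precision 50
  (sd ≈ 0.07 at β = 0.5); betas clipped to [0.02, 0.98] before the
  type-II compression β′ = 0.5 + c(β − 0.5), c = 0.8.
* T-hypermethylation: 200 CpGs, Δβ = +0.4 in T and M over an N baseline
  of 0.2. Metastasis-specific hypomethylation: 120 CpGs, M at 0.25
  against T at 0.65 with N at 0.50, so the set is DM uniquely in M vs T.
* AR-tracking CpGs: 300, β = 0.5 ± (0.08·z + 0.10·sign(z)) in
  metastases, where z is the latent standard-normal AR score and the
  cluster label is sign(z). The 0.20 cluster offset is what makes the
  planted across-sample SD (≈ 0.185) clear the signature filter's
  SD > 0.15 gate with margin; a slope-only design (SD ≈ 0.11) would be
  filtered out by construction. Half the CpGs track positively, half
  negatively (|r| ≈ 0.85 implied).
* Expression: transcript = baseline − 5·β + ε (ε sd 0.7) for
  methylation-coupled genes, giving Pearson r ≈ −0.6; panel genes track
  their latent score with unit slope and noise sd 0.5. AR carries three
  transcripts, like the bead-array annotation it emulates.
* Intensities: lognormal probe levels ×1.6 on the 20-probe AR block of
  amplified metastases (64% amplified by default).
* Survival: exponential with medians 60 (MCA positive) and 30 months
  (MCA negative); censoring is administrative, uniform on (0, 120]
  months for a 20% random subset — the emulated study reports no
  censoring mechanism, so a simple independent one is used.

Inter-probe correlation within promoters is *not* modeled (CpGs are
conditionally independent given the planted structure), there is no
IDAT-level signal model, no batch effects, and no realistic genome-wide
CNV background. Passing recovery tests therefore demonstrates that the
operations recover the structures they are defined on — not that the
thresholds are optimal for real arrays, where co-methylation and
cell-composition effects add correlation the generator lacks.

## Problem sizes and determinism

The default cohort (94 methylomes × 20,000 probes, 90 transcriptomes)
runs end to end in well under a minute on one core and is bit-identical
across runs with the same seed; all randomness flows from
`numpy.random.default_rng` seeded per component via `SeedSequence`. The
test suite exercises recovery on scaled-down cohorts (typically 2,000–
8,400 probes) chosen so each planted structure keeps the same per-probe
effect sizes as the default conditions, and cross-checks every
elementary operation against independent brute-force implementations on
500-probe × 30-sample instances.
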