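# methar

Promoter CpG methylation analysis of prostate-cancer progression, from raw
EPIC-style beta-value matrices to prognostic patient stratification.

The package is aimed at epigenomics analysts working with Infinium-style
methylation arrays of non-malignant prostate (N), primary tumor (T), and
bone-metastasis (M) tissue, together with matched bead-array
transcriptomes. It implements, as a tested and reusable library:

* **Probe filtering and normalization** — beta-mixture quantile (BMIQ)
  normalization of type-II probe chemistry onto the type-I scale,
  exclusion of cross-reactive, meQTL, and SNP-proximal probes (< 5 bp),
  the detection-p rule (p > 0.05 in any sample), and restriction to
  variable promoter CpGs (TSS1500 / TSS200 / 5′UTR, overall SD > 0.05).
* **Delta-beta differential methylation** — a CpG is differentially
  methylated (DM) between groups when |Δβ| = |mean β₁ − mean β₂| > 0.3;
  the three pairwise comparisons are combined into a Venn partition whose
  uniquely-M-vs-T region flags progression-specific CpGs.
* **Methylation–expression integration** — genes classified hyper-down /
  hypo-up when the CpG change is accompanied by an opposite transcript
  change (Wilcoxon rank-sum p < 0.05) with negative Pearson correlation
  between β and transcript level.
* **Pathway-activity scores** — a sample's androgen-receptor (AR)
  activity is its score on the first principal component, *t*[1], of the
  mean-centered expression of an 8-gene AR panel (*AR, FOXA1, HOXB13,
  KLK2, KLK3, NKX3-1, STEAP2, TMPRSS2*); proliferation uses a 28-gene
  cell-cycle panel. The PCA sign ambiguity is fixed by an anchor gene
  (KLK3 / TOP2A, positive loading).
* **The MCA classifier** — the Methylation Classifier for Androgen
  receptor activity: promoter CpGs with |Pearson r| ≥ 0.4 to the AR score
  and SD > 0.15 across metastases. Complete-linkage Euclidean clustering
  on the signature splits metastases into MCA positive / negative (the
  higher-median-AR cluster is positive), with silhouette diagnostics.
* **AR copy-number calls** — per-probe log2 ratios of total array
  intensity against the mean of the non-malignant references,
  median-centered per sample; a region (the AR gene by default) is called
  amplified when its 10%-trimmed mean ratio reaches +0.3.
* **Survival statistics** — Kaplan–Meier curves with the median-
  survival convention min{t : S(t) ≤ 0.5}, the log-rank test, and Cox
  regression (Efron ties) with univariate p < 0.05 gating into the
  multivariate model; plus Wilcoxon tests, Pearson correlation,
  chi-square, and Benjamini–Hochberg FDR.
* **A synthetic-cohort generator** — seeded cohorts (12 N/T pairs, 70
  metastases, 20,000 probes, 90 transcriptomes by default) that plant
  every structure the analysis assumes: T-hypermethylation,
  M-hypomethylation, AR-score-correlated CpG blocks, two latent
  metastasis clusters with 60- vs 30-month survival medians, type-II
  probe compression, inverse methylation–expression coupling, and 1.6×
  AR-region intensity gains.

## Worked example

```python
from methar import CohortConfig, run_all

results = run_all(CohortConfig(seed=2))
s = results["summary"]
print("probes retained:", s["n_probes_retained"])
print("DM-CpGs (T vs N / M vs N / M vs T):",
      s["dm_counts"]["TN"], s["dm_counts"]["MN"], s["dm_counts"]["MT"])
print("uniquely M-vs-T DM-CpGs:", s["unique_mt_count"])
print("MCA signature CpGs:", s["signature_n_cpgs"])
print("MCA clusters:", s["mca_cluster_sizes"])
print("average silhouette width:", round(s["silhouette_average"], 2))
print("AR amplified fraction:", round(s["ar_amplified_fraction"], 2))
print("KM median survival (months):",
      {k: round(v, 1) for k, v in s["km_median_months"].items()})
print("log-rank p:", round(s["logrank_p"], 4))
print("univariate Cox RR, MCA negative:",
      round(s["cox"]["univariate:mca_negative"]["RR"], 2))
```

prints

```
probes retained: 6161
DM-CpGs (T vs N / M vs N / M vs T): 198 205 121
uniquely M-vs-T DM-CpGs: 120
MCA signature CpGs: 300
MCA clusters: {'MCA_positive': 41, 'MCA_negative': 25}
average silhouette width: 0.71
AR amplified fraction: 0.61
KM median survival (months): {'MCA_negative': 24.7, 'MCA_positive': 78.6}
log-rank p: 0.0025
univariate Cox RR, MCA negative: 2.37
```

Reading the output: of 20,000 simulated probes, 6,161 variable promoter
CpGs survive filtering. The T-vs-N comparison recovers the planted
hypermethylation block, and the uniquely-M-vs-T set recovers the planted
metastasis-specific hypomethylation. The MCA signature finds the 300
AR-tracking CpGs, splits the 66 scored metastases into two clusters, and
the MCA-negative cluster — lower AR activity by construction of the label
rule — shows the planted worse survival (hazard ratio ≈ 2.4, log-rank
p ≈ 0.003). The AR amplification call rate matches the planted 64% rate
up to sampling noise.

The same analysis is available from the shell:

```bash
methar run-all --seed 2 --out results/run2/
methar simulate --out cohort/ --seed 7    # just the synthetic tables
```

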