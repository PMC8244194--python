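"""Seeded synthetic prostate-cancer methylation cohorts.

Emulates the structure of a paired primary-tumor series plus a bone-metastasis
series profiled on an EPIC-style methylation array: 12 matched
non-malignant/tumor (N/T) pairs and 70 metastases (M) split into
hormone-naive / short-term castrated / castration-resistant (14/4/52), with
matched transcriptomes for all N/T samples and 66 of the 70 metastases.

Planted structure, all recoverable by the downstream pipeline:

* a block of promoter CpGs hypermethylated in T (and M) versus N;
* a block of promoter CpGs uniquely hypomethylated in M versus T;
* promoter CpGs whose beta tracks a latent per-metastasis androgen-receptor
  (AR) activity score, in both orientations;
* two latent metastasis clusters (the sign of the latent AR score) with an
  extra beta offset on the AR-tracking CpGs and divergent exponential
  survival (default medians 60 vs 30 months);
* negative linear coupling between promoter methylation and the transcript
  of the mapped gene;
* type-II probe compression toward 0.5 (the bead-chemistry bias that
  beta-mixture quantile normalization corrects);
* a 1.6x intensity gain over a 20-probe AR promoter block on chromosome X
  in AR-amplified metastases (64% of M samples by default).

Beta values are drawn from beta distributions around per-probe state means
0.10 / 0.50 / 0.85 with precision 50, clipped to [0.02, 0.98] before
compression. Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats

AR_PANEL = ["AR", "FOXA1", "HOXB13", "KLK2", "KLK3", "NKX3-1", "STEAP2",
            "TMPRSS2"]
PROLIFERATION_PANEL = [
    "RAD54L", "CDC20", "CENPF", "CDKN3", "PBK", "TOP2A", "LCMT2", "ASF1B",
    "KIF20A", "CDCA8", "NUSAP1", "PRC1", "PLK1", "CDCA3", "CEP55", "CDC2",
    "KIF11", "BUB1B", "TK1", "ASPM", "PTTG1", "ORC6L", "FOXM1", "RAD51",
    "CENPM", "CDAN1", "KIAA0101", "MCM10",
]


class ParameterError(io_formats.MetharError):
    """An invalid generator configuration."""


class LabelingError(io_formats.MetharError):
    """A sample label outside the declared vocabulary."""


@dataclass(frozen=True)
class CohortConfig:
    """Cohort shape and planted-effect parameters.

    The defaults reproduce the emulated study conditions; tests may shrink
    counts or turn individual effects off.
    """

    n_pairs: int = 12
    n_met: int = 70
    treatment_split: tuple[int, int, int] = (14, 4, 52)  # HN / ST / CRPC
    n_probes: int = 20_000
    promoter_fraction: float = 0.6
    n_genes: int = 4_000
    n_expr_missing_met: int = 4     # metastases without a transcriptome
    seed: int = 0

    # probe annotation
    type2_fraction: float = 0.84
    cross_reactive_rate: float = 0.02
    meqtl_rate: float = 0.01
    near_snp_rate: float = 0.01
    ar_block_size: int = 20

    # beta-value model
    state_means: tuple[float, float, float] = (0.10, 0.50, 0.85)
    state_weights: tuple[float, float, float] = (0.40, 0.20, 0.40)
    beta_precision: float = 50.0     # inf => noise-free means
    type2_compression: float = 0.8   # beta' = 0.5 + c * (beta - 0.5)

    # planted differential methylation
    n_t_hyper: int = 200
    t_hyper_base: float = 0.20
    t_hyper_delta: float = 0.40
    n_m_hypo: int = 120
    m_hypo_base_t: float = 0.65
    m_hypo_n_offset: float = 0.15    # N sits below T, keeping M-vs-N < 0.3
    m_hypo_delta: float = 0.40

    # AR-activity structure
    n_ar_corr: int = 300
    ar_slope: float = 0.08
    cluster_beta_offset: float = 0.20
    ar_block_means: tuple[float, float] = (0.60, 0.35)   # N/T vs M

    # detection p and intensity
    detp_spoiled_fraction: float = 0.01
    ar_gain: float = 1.6
    ar_amplified_rate: float = 0.64

    # expression model
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    expr_noise_sd: float = 0.7
    methylation_coupling: float = 5.0   # transcript = a - b*beta + eps
    panel_coupling: float = 1.0
    panel_noise_sd: float = 0.5

    # survival
    survival_medians: tuple[float, float] = (60.0, 30.0)  # MCApos, MCAneg
    censor_rate: float = 0.2
    admin_horizon_months: float = 120.0

    def validate(self) -> None:
        if min(self.n_pairs, self.n_met, self.n_probes, self.n_genes) <= 0:
            raise ParameterError("all counts must be positive")
        if sum(self.treatment_split) != self.n_met:
            raise ParameterError(
                f"treatment split {self.treatment_split} does not sum to "
                f"n_met={self.n_met}")
        for name in ("promoter_fraction", "type2_fraction",
                     "cross_reactive_rate", "meqtl_rate", "near_snp_rate",
                     "detp_spoiled_fraction", "ar_amplified_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.type2_compression <= 1.0:
            raise ParameterError("type2_compression must be in (0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must be in [0, 1)")
        if min(self.survival_medians) <= 0:
            raise ParameterError("survival medians must be positive")
        if self.n_expr_missing_met >= self.n_met:
            raise ParameterError("n_expr_missing_met must be < n_met")
        planted = (self.n_t_hyper + self.n_m_hypo + self.n_ar_corr
                   + self.ar_block_size)
        n_promoter_expected = self.promoter_fraction * self.n_probes
        if planted > 0.9 * n_promoter_expected:
            raise ParameterError(
                "planted probe sets exceed the promoter probe budget")
        # planted effects must leave the generating means inside (0, 1)
        for mean in (self.t_hyper_base, self.t_hyper_base + self.t_hyper_delta,
                     self.m_hypo_base_t,
                     self.m_hypo_base_t - self.m_hypo_n_offset,
                     self.m_hypo_base_t - self.m_hypo_delta,
                     *self.ar_block_means):
            if not 0.0 < mean < 1.0:
                raise ParameterError(
                    f"planted effect pushes a group mean to {mean}, outside "
                    "(0, 1)")

    def slope_implied_r(self) -> float:
        """Pearson r between beta and the latent AR score implied by the
        slope and the beta-distribution noise at mean 0.5 (ignoring the
        cluster offset, which only increases the correlation)."""
        if not np.isfinite(self.beta_precision):
            return 1.0
        noise_var = 0.25 / (1.0 + self.beta_precision)
        return self.ar_slope / np.hypot(self.ar_slope, np.sqrt(noise_var))


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator for recovery tests."""

    t_hyper_probes: list[str]
    m_hypo_probes: list[str]
    ar_corr_probes: pd.Series          # probe_id -> slope sign (+1 / -1)
    ar_block_probes: list[str]
    latent_ar_score: pd.Series         # M sample -> score
    latent_prolif_score: pd.Series
    cluster_label: pd.Series           # M sample -> MCApos / MCAneg
    ar_amplified: pd.Series            # M sample -> bool
    survival_median_by_cluster: dict[str, float]
    type2_compression: float
    coupled_genes: dict[str, str]      # probe_id -> gene symbol

    def __post_init__(self) -> None:
        sets = [set(self.t_hyper_probes), set(self.m_hypo_probes),
                set(self.ar_corr_probes.index), set(self.ar_block_probes)]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ParameterError("planted probe sets overlap")
        if not np.isfinite(self.latent_ar_score).all():
            raise ParameterError("latent AR scores must be finite")
        if min(self.survival_median_by_cluster.values()) <= 0:
            raise ParameterError("cluster survival medians must be positive")

    def to_json(self) -> str:
        payload = {
            "t_hyper_probes": self.t_hyper_probes,
            "m_hypo_probes": self.m_hypo_probes,
            "ar_corr_probes": {k: int(v) for k, v in
                               self.ar_corr_probes.items()},
            "ar_block_probes": self.ar_block_probes,
            "latent_ar_score": {k: float(v) for k, v in
                                self.latent_ar_score.items()},
            "latent_prolif_score": {k: float(v) for k, v in
                                    self.latent_prolif_score.items()},
            "cluster_label": dict(self.cluster_label),
            "ar_amplified": {k: bool(v) for k, v in
                             self.ar_amplified.items()},
            "survival_median_by_cluster": self.survival_median_by_cluster,
            "type2_compression": self.type2_compression,
            "coupled_genes": self.coupled_genes,
        }
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticCohort:
    beta: pd.DataFrame
    detp: pd.DataFrame
    intensity: pd.DataFrame
    expr: pd.DataFrame
    gene_map: pd.Series                # transcript_id -> gene symbol
    annotation: pd.DataFrame
    samples: pd.DataFrame
    survival: pd.DataFrame
    truth: PlantedTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_formats.write_matrix(self.beta, outdir / "beta.tsv", "beta")
        io_formats.write_matrix(self.detp, outdir / "detp.tsv", "detp")
        io_formats.write_matrix(self.intensity, outdir / "intensity.tsv",
                                "intensity")
        io_formats.write_matrix(self.expr, outdir / "expression.tsv",
                                "expression")
        self.gene_map.rename("gene").rename_axis("transcript_id") \
            .reset_index().to_csv(outdir / "gene_map.csv", index=False)
        io_formats.write_annotation(self.annotation, outdir / "manifest.csv")
        io_formats.write_sample_sheet(self.samples, outdir / "samples.csv")
        io_formats.write_survival(self.survival, outdir / "survival.csv")
        (outdir / "truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# probe annotation

_AR_TSS = 66_763_874  # hg19-style AR locus on chrX


def generate_probe_annotation(config: CohortConfig) -> pd.DataFrame:
    """Generate an Illumina-manifest-like probe annotation table.

    The last `ar_block_size` probes form a contiguous promoter block of the
    AR gene on chromosome X; all other probes are scattered over autosomes.
    Promoter probes map to TSS1500/TSS200/5UTR of a generic gene; flags are
    independent Bernoulli draws (the AR block is never flagged so that
    copy-number tests retain it).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_probes
    n_ar = config.ar_block_size
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    ar_ids = probe_ids[n - n_ar:]

    chrom = rng.choice([f"chr{c}" for c in range(1, 23)], size=n)
    pos = rng.integers(1, 2**27, size=n)
    strand = rng.choice(["F", "R"], size=n)
    design = np.where(rng.random(n) < config.type2_fraction, "II", "I")
    cross = rng.random(n) < config.cross_reactive_rate
    meqtl = rng.random(n) < config.meqtl_rate
    # near_snp means distance < 5 bp; others get a comfortably large distance
    snp_dist = np.where(rng.random(n) < config.near_snp_rate,
                        rng.integers(0, 5, size=n),
                        rng.integers(5, 1000, size=n)).astype(float)

    promoter = rng.random(n) < config.promoter_fraction
    gene_idx = rng.integers(0, config.n_genes, size=n)
    regions = rng.choice(["TSS1500", "TSS200", "5UTR"], size=n)
    other_regions = rng.choice(["Body", "1stExon", "3UTR"], size=n)
    has_body_mapping = rng.random(n) < 0.7

    pairs: list[list[tuple[str, str]]] = []
    for i in range(n):
        gene = f"G{gene_idx[i]:06d}"
        if promoter[i]:
            pairs.append([(gene, str(regions[i]))])
        elif has_body_mapping[i]:
            pairs.append([(gene, str(other_regions[i]))])
        else:
            pairs.append([])

    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "design_type": design,
            "gene_region_pairs": pairs,
            "cross_reactive": cross,
            "meqtl": meqtl,
            "snp_distance_bp": snp_dist,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    # AR promoter block: contiguous, unflagged, promoter-mapped on chrX
    ann.loc[ar_ids, "chrom"] = "chrX"
    ann.loc[ar_ids, "pos"] = _AR_TSS + 100 * np.arange(n_ar)
    ann.loc[ar_ids, "cross_reactive"] = False
    ann.loc[ar_ids, "meqtl"] = False
    ann.loc[ar_ids, "snp_distance_bp"] = 500.0
    ar_regions = rng.choice(["TSS1500", "TSS200", "5UTR"], size=n_ar)
    for pid, reg in zip(ar_ids, ar_regions):
        ann.at[pid, "gene_region_pairs"] = [("AR", str(reg))]
    ann["near_snp"] = ann["snp_distance_bp"] < 5
    return ann


# ---------------------------------------------------------------------------
# cohort


def _sample_sheet(config: CohortConfig, rng: np.random.Generator,
                  cluster: pd.Series, ar_amp: pd.Series,
                  expr_missing: list[str]) -> pd.DataFrame:
    rows = []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:02d}"
        rows.append((f"N{i + 1:02d}", pid, "N", "NA",
                     rng.uniform(30, 55), "NA", "NA", np.nan,
                     rng.normal(63, 5)))
        rows.append((f"T{i + 1:02d}", pid, "T", "NA",
                     rng.uniform(65, 85), "NA", "NA",
                     rng.lognormal(np.log(11), 0.5), rng.normal(63, 5)))
    n_hn, n_st, n_crpc = config.treatment_split
    treatments = ["HN"] * n_hn + ["ST"] * n_st + ["CRPC"] * n_crpc
    for j in range(config.n_met):
        sid = f"M{j + 1:02d}"
        if sid in expr_missing:
            subtype = "NA"
        elif cluster[sid] == "MCApos":
            subtype = rng.choice(["MetA", "MetB", "MetC"], p=[0.8, 0.08, 0.12])
        else:
            subtype = rng.choice(["MetA", "MetB", "MetC"], p=[0.35, 0.40, 0.25])
        psa_mu = np.log(250) if cluster[sid] == "MCApos" else np.log(90)
        rows.append((sid, f"MP{j + 1:02d}", "M", treatments[j],
                     rng.uniform(45, 85), subtype,
                     str(bool(ar_amp[sid])).lower(),
                     rng.lognormal(psa_mu, 0.8), rng.normal(73, 5)))
    sheet = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "tissue", "treatment",
                 "epithelial_fraction", "met_subtype", "ar_amplified",
                 "serum_psa", "age"],
    ).set_index("sample_id")
    sheet["epithelial_fraction"] = sheet["epithelial_fraction"].round(0)
    return sheet


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with recorded ground truth."""
    config.validate()
    annotation = generate_probe_annotation(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_probes = config.n_probes
    probe_ids = list(annotation.index)
    ar_block = annotation.index[annotation["chrom"] == "chrX"].tolist()

    n_samples = [f"N{i + 1:02d}" for i in range(config.n_pairs)]
    t_samples = [f"T{i + 1:02d}" for i in range(config.n_pairs)]
    m_samples = [f"M{j + 1:02d}" for j in range(config.n_met)]
    sample_ids = n_samples + t_samples + m_samples

    # latent metastasis structure: standard-normal AR score, cluster = sign
    latent_ar = pd.Series(rng.standard_normal(config.n_met), index=m_samples)
    cluster = pd.Series(np.where(latent_ar >= 0, "MCApos", "MCAneg"),
                        index=m_samples)
    # proliferation runs modestly opposite to the AR program
    latent_prolif = pd.Series(
        np.where(cluster == "MCAneg", 0.5, -0.5)
        + rng.standard_normal(config.n_met), index=m_samples)
    ar_amp = pd.Series(rng.random(config.n_met) < config.ar_amplified_rate,
                       index=m_samples)

    # planted probe sets: drawn from unflagged promoter probes (excluding
    # the AR block) so that every planted probe survives filtering
    is_promoter = annotation["gene_region_pairs"].map(
        lambda ps: any(r in io_formats.PROMOTER_REGIONS for _, r in ps))
    eligible = annotation.index[
        is_promoter & ~annotation["cross_reactive"] & ~annotation["meqtl"]
        & ~annotation["near_snp"] & (annotation["chrom"] != "chrX")
    ].to_numpy()
    n_needed = config.n_t_hyper + config.n_m_hypo + config.n_ar_corr
    if n_needed > len(eligible):
        raise ParameterError("not enough eligible promoter probes to plant")
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    t_hyper = list(chosen[:config.n_t_hyper])
    m_hypo = list(chosen[config.n_t_hyper:config.n_t_hyper + config.n_m_hypo])
    ar_corr = list(chosen[config.n_t_hyper + config.n_m_hypo:])
    ar_signs = pd.Series(
        np.where(np.arange(config.n_ar_corr) < config.n_ar_corr // 2, 1, -1),
        index=ar_corr, dtype=int)

    # give planted probes distinct gene symbols so that gene-level
    # integration has a one-to-one probe/gene correspondence
    coupled_genes: dict[str, str] = {}
    for k, pid in enumerate(t_hyper):
        coupled_genes[pid] = f"TH{k:04d}"
    for k, pid in enumerate(m_hypo):
        coupled_genes[pid] = f"MH{k:04d}"
    for k, pid in enumerate(ar_corr):
        coupled_genes[pid] = f"AC{k:04d}"
    for pid, gene in coupled_genes.items():
        old = annotation.at[pid, "gene_region_pairs"]
        region = old[0][1] if old else "TSS200"
        annotation.at[pid, "gene_region_pairs"] = [(gene, region)]

    # --- group-mean matrix -------------------------------------------------
    idx = pd.Index(probe_ids)
    row = {pid: i for i, pid in enumerate(probe_ids)}
    n_cols = np.arange(0, config.n_pairs)
    t_cols = np.arange(config.n_pairs, 2 * config.n_pairs)
    m_cols = np.arange(2 * config.n_pairs, 2 * config.n_pairs + config.n_met)

    states = rng.choice(config.state_means, size=n_probes,
                        p=config.state_weights)
    mu = np.tile(states[:, None], (1, len(sample_ids)))

    r_th = [row[p] for p in t_hyper]
    mu[r_th, :] = config.t_hyper_base
    mu[np.ix_(r_th, t_cols)] += config.t_hyper_delta
    mu[np.ix_(r_th, m_cols)] += config.t_hyper_delta

    r_mh = [row[p] for p in m_hypo]
    mu[r_mh, :] = config.m_hypo_base_t
    mu[np.ix_(r_mh, n_cols)] -= config.m_hypo_n_offset
    mu[np.ix_(r_mh, m_cols)] -= config.m_hypo_delta

    r_ac = [row[p] for p in ar_corr]
    mu[r_ac, :] = 0.5
    signs = ar_signs.to_numpy()[:, None]
    cluster_sign = np.where(cluster.to_numpy() == "MCApos", 1.0, -1.0)[None, :]
    shift = signs * (config.ar_slope * latent_ar.to_numpy()[None, :]
                     + 0.5 * config.cluster_beta_offset * cluster_sign)
    mu[np.ix_(r_ac, m_cols)] = 0.5 + shift

    r_ar = [row[p] for p in ar_block]
    mu[r_ar, :] = config.ar_block_means[0]
    mu[np.ix_(r_ar, m_cols)] = config.ar_block_means[1]

    mu = np.clip(mu, 0.05, 0.95)

    # --- beta draws, clipping, type-II compression -------------------------
    if np.isfinite(config.beta_precision):
        a = mu * config.beta_precision
        b = (1.0 - mu) * config.beta_precision
        beta = rng.beta(a, b)
    else:
        beta = mu.copy()
    beta = np.clip(beta, 0.02, 0.98)
    type2 = (annotation["design_type"] == "II").to_numpy()
    c = config.type2_compression
    beta[type2, :] = 0.5 + c * (beta[type2, :] - 0.5)
    beta_df = pd.DataFrame(beta, index=idx.rename("probe_id"),
                           columns=sample_ids)

    # --- detection p -------------------------------------------------------
    detp = rng.uniform(0.0005, 0.008, size=beta.shape)
    n_spoiled = int(round(config.detp_spoiled_fraction * n_probes))
    if n_spoiled:
        spoil_candidates = np.setdiff1d(
            np.arange(n_probes), np.array(r_th + r_mh + r_ac + r_ar))
        spoiled = rng.choice(spoil_candidates, size=n_spoiled, replace=False)
        cols = rng.integers(0, len(sample_ids), size=n_spoiled)
        detp[spoiled, cols] = rng.uniform(0.06, 0.5, size=n_spoiled)
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=sample_ids)

    # --- intensity ---------------------------------------------------------
    probe_level = rng.lognormal(np.log(5000.0), 0.10, size=n_probes)
    noise = rng.lognormal(0.0, 0.05, size=beta.shape)
    intensity = probe_level[:, None] * noise
    amp_cols = m_cols[ar_amp.to_numpy()]
    intensity[np.ix_(r_ar, amp_cols)] *= config.ar_gain
    intensity_df = pd.DataFrame(intensity, index=beta_df.index,
                                columns=sample_ids)

    # --- expression --------------------------------------------------------
    expr_missing = sorted(rng.choice(m_samples,
                                     size=config.n_expr_missing_met,
                                     replace=False))
    expr_samples = [s for s in sample_ids if s not in expr_missing]
    m_expr = [s for s in m_samples if s not in expr_missing]

    special = list(dict.fromkeys(
        AR_PANEL + PROLIFERATION_PANEL + sorted(coupled_genes.values())))
    n_generic = config.n_genes - len(special)
    if n_generic < 0:
        raise ParameterError("n_genes too small for panels + planted genes")
    genes = special + [f"G{i:06d}" for i in range(n_generic)]
    transcripts = [f"{g}_t1" for g in genes] + ["AR_t2", "AR_t3"]
    gene_map = pd.Series([t.rsplit("_t", 1)[0] for t in transcripts],
                         index=pd.Index(transcripts, name="transcript_id"),
                         name="gene")

    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd,
                          size=len(transcripts))
    expr = baseline[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(len(transcripts), len(expr_samples)))
    expr_df = pd.DataFrame(expr, index=gene_map.index, columns=expr_samples)

    trans_of_gene: dict[str, list[str]] = {}
    for t, g in gene_map.items():
        trans_of_gene.setdefault(g, []).append(t)

    # methylation-coupled transcripts: a - b*beta + noise
    for pid, gene in coupled_genes.items():
        bvals = beta_df.loc[pid, expr_samples].to_numpy()
        for t in trans_of_gene[gene]:
            expr_df.loc[t] = (baseline[transcripts.index(t)]
                              + config.methylation_coupling * (0.5 - bvals)
                              + rng.normal(0, config.expr_noise_sd,
                                           len(expr_samples)))
    # AR-program and proliferation panels track their latent scores in M
    ar_vals = latent_ar[m_expr].to_numpy()
    prolif_vals = latent_prolif[m_expr].to_numpy()
    for gene in AR_PANEL:
        for t in trans_of_gene[gene]:
            expr_df.loc[t, m_expr] = (
                baseline[transcripts.index(t)]
                + config.panel_coupling * ar_vals
                + rng.normal(0, config.panel_noise_sd, len(m_expr)))
    for gene in PROLIFERATION_PANEL:
        for t in trans_of_gene[gene]:
            expr_df.loc[t, m_expr] = (
                baseline[transcripts.index(t)]
                + config.panel_coupling * prolif_vals
                + rng.normal(0, config.panel_noise_sd, len(m_expr)))
    # amplified metastases get an extra AR transcript boost
    amp_expr = [s for s in m_expr if ar_amp[s]]
    if amp_expr:
        expr_df.loc[["AR_t1", "AR_t2", "AR_t3"], amp_expr] += 0.5

    # --- survival ----------------------------------------------------------
    medians = {"MCApos": config.survival_medians[0],
               "MCAneg": config.survival_medians[1]}
    patient_of = {f"M{j + 1:02d}": f"MP{j + 1:02d}"
                  for j in range(config.n_met)}
    survival = plant_survival(
        cluster.rename(index=patient_of), medians,
        censor_rate=config.censor_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        admin_horizon=config.admin_horizon_months)

    samples = _sample_sheet(config, rng, cluster, ar_amp, expr_missing)
    truth = PlantedTruth(
        t_hyper_probes=t_hyper,
        m_hypo_probes=m_hypo,
        ar_corr_probes=ar_signs,
        ar_block_probes=ar_block,
        latent_ar_score=latent_ar,
        latent_prolif_score=latent_prolif,
        cluster_label=cluster,
        ar_amplified=ar_amp,
        survival_median_by_cluster=medians,
        type2_compression=config.type2_compression,
        coupled_genes=coupled_genes,
    )
    return SyntheticCohort(beta=beta_df, detp=detp_df, intensity=intensity_df,
                           expr=expr_df, gene_map=gene_map,
                           annotation=annotation, samples=samples,
                           survival=survival, truth=truth)


def plant_survival(cluster_label: pd.Series, medians: dict[str, float],
                   censor_rate: float = 0.0, seed: int = 0,
                   admin_horizon: float = 120.0) -> pd.DataFrame:
    """Exponential survival times per cluster with independent censoring.

    Event times are exponential with rate ln(2)/median for the subject's
    cluster. A fraction `censor_rate` of subjects receives an independent
    administrative censoring time uniform on (0, admin_horizon]; the
    observed time is the minimum and the event flag marks death (1) versus
    censoring (0).
    """
    if min(medians.values()) <= 0:
        raise ParameterError("survival medians must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ParameterError("censor_rate must be in [0, 1)")
    unknown = set(cluster_label.unique()) - set(medians)
    if unknown:
        raise LabelingError(f"unknown cluster label(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rates = cluster_label.map(lambda lab: np.log(2) / medians[lab])
    times = rng.exponential(1.0 / rates.to_numpy())
    censored = rng.random(len(times)) < censor_rate
    ctimes = np.where(censored,
                      rng.uniform(0.0, admin_horizon, size=len(times)),
                      np.inf)
    months = np.minimum(times, ctimes)
    months = np.maximum(months, 1e-3)  # follow-up strictly positive
    event = (times <= ctimes).astype(int)
    return pd.DataFrame(
        {"months": months, "event": event,
         "cluster": cluster_label.to_numpy()},
        index=pd.Index(cluster_label.index, name="patient_id"))


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a CohortConfig from a YAML mapping of field overrides."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown config field(s) {sorted(unknown)}")
    for key in ("treatment_split", "state_means", "state_weights",
                "survival_medians", "ar_block_means"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortConfig(**data)
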