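"""Delta-beta differential methylation and methylation-expression
integration.

A CpG is differentially methylated (DM) between two tissue groups when the
difference of group-mean betas exceeds 0.3 in absolute value (strict
inequality). The three pairwise comparisons (T vs N, M vs N, M vs T) are
combined into a Venn partition; the uniquely-M-vs-T set (DM in M vs T but
in neither other comparison) flags CpGs tied to metastatic progression
rather than to the tissue of origin.

Integration couples each DM gene to its transcript(s): a gene is
"hyper-down" when the CpG is hypermethylated, the transcript is lower in
the hypermethylated group with Wilcoxon rank-sum p below the gate, and
methylation and expression correlate negatively ("hypo-up" symmetrically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstats
from .io_formats import MetharError, promoter_genes

log = logging.getLogger("methar")


class GroupingError(MetharError):
    pass


@dataclass
class DMRecord:
    probe_id: str
    mean_group1: float
    mean_group2: float
    delta_beta: float                    # mean(group1) - mean(group2)
    direction: str                       # hyper/hypo w.r.t. group1
    gene_region_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class DMPartition:
    """Venn partition of three DM-CpG sets (TN, MN, MT)."""

    regions: dict[str, set[str]]         # keys like "TN", "TN&MN", ...
    unique_mt: set[str]
    hyper_hypo: dict[str, dict[str, int]]

    @property
    def region_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


@dataclass
class IntegrationRecord:
    gene: str
    probe_id: str
    transcript_id: str | None
    meth_direction: str                  # hyper/hypo
    expr_log_fold: float                 # mean(group1) - mean(group2)
    p_expression: float
    p_expression_bh: float
    pearson_r: float
    classification: str                  # hyper-down/hypo-up/discordant/ns/no-data


def call_dm_cpgs(beta: pd.DataFrame, samples: pd.DataFrame,
                 group1: str, group2: str, threshold: float = 0.3,
                 annotation: pd.DataFrame | None = None) -> list[DMRecord]:
    """Emit probes with |mean(group1) - mean(group2)| strictly > threshold.

    `group1`/`group2` are tissue labels resolved against the sample sheet.
    Direction is "hyper" when group1 has the higher mean.
    """
    ids1 = samples.index[samples["tissue"] == group1]
    ids2 = samples.index[samples["tissue"] == group2]
    return call_dm_cpgs_by_samples(beta, list(ids1), list(ids2),
                                   threshold=threshold, annotation=annotation)


def call_dm_cpgs_by_samples(beta: pd.DataFrame, ids1: list[str],
                            ids2: list[str], threshold: float = 0.3,
                            annotation: pd.DataFrame | None = None
                            ) -> list[DMRecord]:
    if not ids1 or not ids2:
        raise GroupingError("both groups must be non-empty")
    overlap = set(ids1) & set(ids2)
    if overlap:
        raise GroupingError(f"samples in both groups: {sorted(overlap)}")
    m1 = beta[ids1].mean(axis=1)
    m2 = beta[ids2].mean(axis=1)
    delta = m1 - m2
    hits = delta.abs() > threshold
    records = []
    for pid in beta.index[hits]:
        pairs = []
        if annotation is not None and pid in annotation.index:
            pairs = list(annotation.at[pid, "gene_region_pairs"])
        records.append(DMRecord(
            probe_id=pid,
            mean_group1=float(m1[pid]),
            mean_group2=float(m2[pid]),
            delta_beta=float(delta[pid]),
            direction="hyper" if delta[pid] > 0 else "hypo",
            gene_region_pairs=pairs,
        ))
    return records


def partition_dm_sets(dm_tn: list[DMRecord], dm_mn: list[DMRecord],
                      dm_mt: list[DMRecord]) -> DMPartition:
    """All 7 Venn regions of the three DM sets plus direction tallies."""
    tn = {r.probe_id for r in dm_tn}
    mn = {r.probe_id for r in dm_mn}
    mt = {r.probe_id for r in dm_mt}
    regions = {
        "TN": tn - mn - mt,
        "MN": mn - tn - mt,
        "MT": mt - tn - mn,
        "TN&MN": (tn & mn) - mt,
        "TN&MT": (tn & mt) - mn,
        "MN&MT": (mn & mt) - tn,
        "TN&MN&MT": tn & mn & mt,
    }
    hyper_hypo = {}
    for name, recs in (("TN", dm_tn), ("MN", dm_mn), ("MT", dm_mt)):
        hyper_hypo[name] = {
            "hyper": sum(r.direction == "hyper" for r in recs),
            "hypo": sum(r.direction == "hypo" for r in recs),
        }
    return DMPartition(regions=regions, unique_mt=mt - (tn | mn),
                       hyper_hypo=hyper_hypo)


def integrate_methylation_expression(
        dm: list[DMRecord], beta: pd.DataFrame, expr: pd.DataFrame,
        gene_map: pd.Series, ids1: list[str], ids2: list[str],
        p_max: float = 0.05, r_max: float | None = None
        ) -> list[IntegrationRecord]:
    """Classify DM genes by coupled expression change.

    For each DM probe and each transcript of any promoter-mapped gene:
    Wilcoxon rank-sum between the two sample groups on transcript level,
    Pearson r between beta and transcript across those samples, then
    classification: hyper-down (hyper CpG, expression down, p < p_max,
    r < 0 or r < -r_max when set), hypo-up symmetrically, discordant when
    significant but in the non-inverse direction, else ns. Genes without
    expression data are emitted as "no-data" rather than dropped; BH-
    adjusted p-values are reported alongside (classification uses the
    unadjusted p).
    """
    expr_ids1 = [s for s in ids1 if s in expr.columns]
    expr_ids2 = [s for s in ids2 if s in expr.columns]
    transcripts_of: dict[str, list[str]] = {}
    for t, g in gene_map.items():
        if t in expr.index:
            transcripts_of.setdefault(g, []).append(t)

    records: list[IntegrationRecord] = []
    for rec in dm:
        genes = promoter_genes(rec.gene_region_pairs) or \
            [g for g, _ in rec.gene_region_pairs]
        for gene in genes:
            transcripts = transcripts_of.get(gene, [])
            if not transcripts or len(expr_ids1) < 3 or len(expr_ids2) < 3:
                records.append(IntegrationRecord(
                    gene=gene, probe_id=rec.probe_id, transcript_id=None,
                    meth_direction=rec.direction, expr_log_fold=np.nan,
                    p_expression=np.nan, p_expression_bh=np.nan,
                    pearson_r=np.nan, classification="no-data"))
                continue
            for t in transcripts:
                e1 = expr.loc[t, expr_ids1].to_numpy(dtype=float)
                e2 = expr.loc[t, expr_ids2].to_numpy(dtype=float)
                fold = float(e1.mean() - e2.mean())
                if np.all(np.concatenate([e1, e2])
                          == np.concatenate([e1, e2])[0]):
                    records.append(IntegrationRecord(
                        gene=gene, probe_id=rec.probe_id, transcript_id=t,
                        meth_direction=rec.direction, expr_log_fold=0.0,
                        p_expression=1.0, p_expression_bh=np.nan,
                        pearson_r=np.nan, classification="ns"))
                    continue
                _, p = survstats.wilcoxon_test(e1, e2, paired=False)
                both = expr_ids1 + expr_ids2
                bvals = beta.loc[rec.probe_id, both].to_numpy(dtype=float)
                evals = expr.loc[t, both].to_numpy(dtype=float)
                if np.std(bvals) == 0 or np.std(evals) == 0:
                    r = np.nan
                else:
                    r, _ = survstats.pearson_correlation(bvals, evals)
                records.append(IntegrationRecord(
                    gene=gene, probe_id=rec.probe_id, transcript_id=t,
                    meth_direction=rec.direction, expr_log_fold=fold,
                    p_expression=p, p_expression_bh=np.nan, pearson_r=r,
                    classification=_classify(rec.direction, fold, p, r,
                                             p_max, r_max)))
    # BH adjustment over all tested transcripts, reported for transparency
    tested = [r for r in records if np.isfinite(r.p_expression)]
    if tested:
        adjusted = survstats.bh_fdr([r.p_expression for r in tested])
        for r, padj in zip(tested, adjusted):
            r.p_expression_bh = float(padj)
    return records


def _classify(direction: str, fold: float, p: float, r: float,
              p_max: float, r_max: float | None) -> str:
    if not p < p_max:
        return "ns"
    r_ok_neg = (r < 0) if r_max is None else (r < -r_max)
    if direction == "hyper" and fold < 0 and r_ok_neg:
        return "hyper-down"
    if direction == "hypo" and fold > 0 and r_ok_neg:
        return "hypo-up"
    return "discordant"


def classify_genes(records: list[IntegrationRecord]) -> dict[str, str]:
    """Gene-level call: the most significant concordant transcript wins;
    otherwise ns/no-data."""
    best: dict[str, IntegrationRecord] = {}
    for rec in records:
        cur = best.get(rec.gene)
        if cur is None:
            best[rec.gene] = rec
            continue
        rank = {"hyper-down": 0, "hypo-up": 0, "discordant": 1, "ns": 2,
                "no-data": 3}
        key_new = (rank[rec.classification],
                   rec.p_expression if np.isfinite(rec.p_expression) else 1.1)
        key_cur = (rank[cur.classification],
                   cur.p_expression if np.isfinite(cur.p_expression) else 1.1)
        if key_new < key_cur:
            best[rec.gene] = rec
    return {g: r.classification for g, r in best.items()}


def dm_records_frame(records: list[DMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "mean_group1": [r.mean_group1 for r in records],
            "mean_group2": [r.mean_group2 for r in records],
            "delta_beta": [r.delta_beta for r in records],
            "direction": [r.direction for r in records],
            "genes": [";".join(g for g, _ in r.gene_region_pairs)
                      for r in records],
        }
    )


def integration_frame(records: list[IntegrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "probe_id": [r.probe_id for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "meth_direction": [r.meth_direction for r in records],
            "expr_log_fold": [r.expr_log_fold for r in records],
            "p_expression": [r.p_expression for r in records],
            "p_expression_bh": [r.p_expression_bh for r in records],
            "pearson_r": [r.pearson_r for r in records],
            "classification": [r.classification for r in records],
        }
    )
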