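"""The Methylation Classifier for Androgen receptor activity (MCA).

Promoter CpGs whose beta level tracks the per-metastasis AR activity score
(|Pearson r| >= 0.4 with across-sample SD > 0.15) form the MCA signature.
Agglomerative clustering of the metastasis samples on the signature CpGs
(Euclidean distance, complete linkage, tree cut at k = 2) yields two
clusters; the one with the higher median AR score is labeled MCA positive.
MCA-negative status marks low-AR-activity metastases with worse prognosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, fcluster, dendrogram
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_samples

from . import survstats
from .io_formats import MetharError, promoter_genes

log = logging.getLogger("methar")


class SignatureError(MetharError):
    pass


@dataclass
class MCASignature:
    """Selected CpGs with their correlation to the AR score."""

    entries: pd.DataFrame     # index probe_id; columns pearson_r, sd, sign
    r_min: float
    sd_min: float
    samples: list[str]

    @property
    def probes(self) -> list[str]:
        return list(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClusterAssignment:
    labels: pd.Series          # sample_id -> MCA_positive / MCA_negative
    linkage: str
    median_ar: dict[str, float]
    linkage_matrix: np.ndarray | None = None


@dataclass
class SilhouetteResult:
    widths: pd.Series
    average: float


def select_mca_cpgs(beta_m: pd.DataFrame, ar_scores: pd.Series,
                    r_min: float = 0.4, sd_min: float = 0.15
                    ) -> MCASignature:
    """Select signature CpGs: SD > sd_min and |Pearson r| >= r_min.

    `beta_m` must be restricted to metastasis samples that carry an AR
    score; probes with zero variance are excluded before the correlation
    (r undefined).
    """
    samples = [s for s in beta_m.columns if s in ar_scores.index]
    if len(samples) < 3:
        raise SignatureError("need >= 3 scored samples for correlation")
    sub = beta_m[samples]
    score = ar_scores[samples].to_numpy(dtype=float)
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    variable = sd > 0
    # vectorized Pearson r against the score
    centered = values - values.mean(axis=1, keepdims=True)
    s_centered = score - score.mean()
    denom = (np.sqrt((centered ** 2).sum(axis=1))
             * np.sqrt((s_centered ** 2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, centered @ s_centered / denom, np.nan)
    keep = variable & (sd > sd_min) & (np.abs(r) >= r_min)
    entries = pd.DataFrame(
        {"pearson_r": r[keep], "sd": sd[keep],
         "sign": np.where(r[keep] >= 0, "pos", "neg")},
        index=sub.index[keep])
    return MCASignature(entries=entries, r_min=r_min, sd_min=sd_min,
                        samples=samples)


def cluster_and_label_mca(beta_m: pd.DataFrame, signature: MCASignature,
                          ar_scores: pd.Series,
                          metric: str = "euclidean",
                          linkage_method: str = "complete"
                          ) -> ClusterAssignment:
    """Two-cluster agglomerative assignment on signature-CpG betas.

    Samples are clustered on the signature CpGs (default Euclidean
    distance, complete linkage, cut at k = 2); the cluster with the higher
    median AR score becomes MCA_positive.
    """
    if len(signature) == 0:
        raise SignatureError("empty signature")
    samples = [s for s in beta_m.columns if s in signature.samples]
    data = beta_m.loc[signature.probes, samples].to_numpy(dtype=float).T
    dist = pdist(data, metric=metric)
    if linkage_method != "complete":
        from scipy.cluster.hierarchy import linkage as _linkage
        z = _linkage(dist, method=linkage_method)
    else:
        z = complete(dist)
    raw = fcluster(z, t=2, criterion="maxclust")
    labels = pd.Series(raw, index=samples)
    counts = labels.value_counts()
    if counts.min() == 1:
        log.warning("cluster_and_label_mca: singleton cluster")
    medians = {
        int(c): float(ar_scores[labels.index[labels == c]].median())
        for c in counts.index
    }
    if len(medians) == 2:
        pos_cluster = max(medians, key=lambda c: medians[c])
    else:
        pos_cluster = list(medians)[0]
    named = labels.map(lambda c: "MCA_positive" if c == pos_cluster
                       else "MCA_negative")
    median_ar = {("MCA_positive" if c == pos_cluster else "MCA_negative"): m
                 for c, m in medians.items()}
    return ClusterAssignment(labels=named, linkage=f"{metric}/"
                             f"{linkage_method}", median_ar=median_ar,
                             linkage_matrix=z)


def silhouette_widths(data: pd.DataFrame | np.ndarray,
                      labels: pd.Series | np.ndarray,
                      metric: str = "euclidean") -> SilhouetteResult:
    """Per-sample silhouette width s(i) = (b - a) / max(a, b).

    `data` is samples x features (or a precomputed square distance matrix
    with metric="precomputed"); singleton-cluster samples and degenerate
    a = b = 0 cases get width 0.
    """
    if isinstance(data, pd.DataFrame):
        index = data.index
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        index = pd.RangeIndex(len(values))
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise SignatureError("silhouette needs >= 2 clusters")
    widths = silhouette_samples(values, lab, metric=metric)
    widths = np.nan_to_num(widths, nan=0.0)
    series = pd.Series(widths, index=index)
    return SilhouetteResult(widths=series, average=float(series.mean()))


def mca_gene_lists(signature: MCASignature, beta_m: pd.DataFrame,
                   expr: pd.DataFrame, gene_map: pd.Series,
                   annotation: pd.DataFrame,
                   inverse_r_min: float = 0.4) -> dict[str, list[str]]:
    """Genes per signature sign block with inverse methylation-expression
    coupling (Pearson r between beta and transcript < -inverse_r_min),
    exported for external enrichment. Genes lacking expression data are
    listed under "<sign>_no_expression"."""
    transcripts_of: dict[str, list[str]] = {}
    for t, g in gene_map.items():
        if t in expr.index:
            transcripts_of.setdefault(g, []).append(t)
    out: dict[str, list[str]] = {"pos": [], "neg": [],
                                 "pos_no_expression": [],
                                 "neg_no_expression": []}
    for pid, row in signature.entries.iterrows():
        if pid not in annotation.index:
            continue
        genes = promoter_genes(annotation.at[pid, "gene_region_pairs"])
        samples = [s for s in signature.samples if s in expr.columns]
        bvals = beta_m.loc[pid, samples].to_numpy(dtype=float)
        for gene in genes:
            transcripts = transcripts_of.get(gene, [])
            if not transcripts:
                key = f"{row['sign']}_no_expression"
                if gene not in out[key]:
                    out[key].append(gene)
                continue
            for t in transcripts:
                evals = expr.loc[t, samples].to_numpy(dtype=float)
                if np.std(bvals) == 0 or np.std(evals) == 0:
                    continue
                r, _ = survstats.pearson_correlation(bvals, evals)
                if r < -inverse_r_min:
                    if gene not in out[row["sign"]]:
                        out[row["sign"]].append(gene)
                    break
    return out


def dendrogram_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick-style string."""
    n = len(leaf_names)
    trees: dict[int, str] = {i: leaf_names[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, height, _) in enumerate(z):
        a, b = int(a), int(b)
        la = max(height - heights[a], 0.0)
        lb = max(height - heights[b], 0.0)
        trees[n + k] = f"({trees[a]}:{la:.6g},{trees[b]}:{lb:.6g})"
        heights[n + k] = height
    return trees[n + len(z) - 1] + ";"
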