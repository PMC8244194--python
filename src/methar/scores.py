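"""PCA machinery and fixed-panel t[1] activity scores.

A sample's pathway activity is summarized by its score on the first
principal component (t[1]) of the mean-centered expression submatrix of a
fixed gene panel. PCA's sign ambiguity is resolved by an anchor gene: the
component is flipped so the anchor's loading is positive (KLK3 for the
androgen-receptor panel, TOP2A for the proliferation panel — canonical
positive markers of each program).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MetharError
from .synthdata import AR_PANEL, PROLIFERATION_PANEL

log = logging.getLogger("methar")

# historic HGNC symbols that appear in legacy panels / array annotations
SYMBOL_ALIASES = {
    "CDC2": "CDK1",
    "ORC6L": "ORC6",
    "KIAA0101": "PCLAF",
    "CDAN1": "CDIN1",
}


class PanelCoverageError(MetharError):
    pass


class OrientationError(MetharError):
    pass


class PCAError(MetharError):
    pass


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: tuple[str, ...]
    anchor: str

    def __post_init__(self) -> None:
        if self.anchor not in self.genes:
            raise OrientationError(
                f"anchor {self.anchor!r} not in panel {self.name!r}")
        if len(set(self.genes)) != len(self.genes):
            raise MetharError(f"panel {self.name!r} has duplicate symbols")


AR_ACTIVITY_PANEL = GenePanel("ar_activity", tuple(AR_PANEL), anchor="KLK3")
PROLIFERATION_SCORE_PANEL = GenePanel(
    "proliferation", tuple(PROLIFERATION_PANEL), anchor="TOP2A")


@dataclass
class ScoreVector:
    panel: str
    scores: pd.Series                 # sample_id -> t[1]
    loadings: pd.Series               # transcript_id -> loading on PC1
    explained_variance_ratio: float
    genes_found: list[str] = field(default_factory=list)
    genes_missing: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        total = len(self.genes_found) + len(self.genes_missing)
        return len(self.genes_found) / total if total else 0.0


def pca_scores(matrix: pd.DataFrame, center: bool = True,
               n_components: int | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a features x samples matrix via SVD.

    Returns (scores: samples x components, loadings: features x
    components, explained variance ratios). The matrix is mean-centered
    per feature unless `center` is False; missing values are rejected.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 1:
        raise PCAError("need >= 2 samples and >= 1 feature")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise PCAError("matrix contains missing/non-finite values")
    if center:
        values = values - values.mean(axis=1, keepdims=True)
    # samples x features orientation for the decomposition
    x = values.T
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape) if n_components is None else min(n_components,
                                                      min(x.shape))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    total_var = (s ** 2).sum()
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    comp = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=matrix.columns, columns=comp),
            pd.DataFrame(loadings, index=matrix.index, columns=comp),
            evr)


def resolve_panel_transcripts(panel: GenePanel, gene_map: pd.Series
                              ) -> tuple[dict[str, list[str]], list[str]]:
    """Map panel genes to transcript ids, honoring historic symbol
    aliases in both directions. Returns (gene -> transcripts, missing)."""
    by_gene: dict[str, list[str]] = {}
    for t, g in gene_map.items():
        by_gene.setdefault(g, []).append(t)
    found: dict[str, list[str]] = {}
    missing: list[str] = []
    for gene in panel.genes:
        candidates = [gene, SYMBOL_ALIASES.get(gene, gene)]
        candidates += [old for old, new in SYMBOL_ALIASES.items()
                       if new == gene]
        hits: list[str] = []
        for cand in dict.fromkeys(candidates):
            hits.extend(by_gene.get(cand, []))
        if hits:
            found[gene] = hits
        else:
            missing.append(gene)
    return found, missing


def panel_score(expr: pd.DataFrame, panel: GenePanel,
                gene_map: pd.Series, samples: list[str] | None = None,
                min_coverage: float = 0.75) -> ScoreVector:
    """t[1] score of each sample over a gene panel.

    Subsets expression to the panel transcripts and requested samples,
    mean-centers per transcript, takes the first principal component, and
    orients it so the anchor gene's loading is positive.
    """
    if samples is None:
        samples = list(expr.columns)
    unknown = set(samples) - set(expr.columns)
    if unknown:
        raise MetharError(f"samples not in expression matrix: "
                          f"{sorted(unknown)[:5]}")
    found, missing = resolve_panel_transcripts(panel, gene_map)
    coverage = len(found) / len(panel.genes)
    if coverage < min_coverage:
        raise PanelCoverageError(
            f"panel {panel.name!r}: only {len(found)}/{len(panel.genes)} "
            f"genes present (need >= {min_coverage:.0%})")
    if panel.anchor not in found:
        raise OrientationError(
            f"anchor gene {panel.anchor!r} missing from expression data")
    transcripts = [t for gene in panel.genes for t in found.get(gene, [])]
    sub = expr.loc[transcripts, samples]
    if len(transcripts) == 1:
        centered = sub.iloc[0] - sub.iloc[0].mean()
        scores = centered.astype(float)
        loadings = pd.Series([1.0], index=sub.index)
        evr = 1.0
    else:
        score_df, loading_df, evr_all = pca_scores(sub, center=True,
                                                   n_components=1)
        scores = score_df["PC1"]
        loadings = loading_df["PC1"]
        evr = float(evr_all[0])
    anchor_loading = loadings.loc[found[panel.anchor]].mean()
    if anchor_loading < 0:
        scores = -scores
        loadings = -loadings
    return ScoreVector(panel=panel.name, scores=scores, loadings=loadings,
                       explained_variance_ratio=evr,
                       genes_found=sorted(found),
                       genes_missing=sorted(missing))
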