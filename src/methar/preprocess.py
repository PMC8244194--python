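"""Probe filtering and normalization for methylation and expression data.

The methylation flow runs in a fixed order: beta-mixture quantile (BMIQ)
normalization of the type-II probe chemistry onto the type-I scale, then
exclusion-list probe filters (cross-reactive, meQTL, SNP-proximal) and the
detection-p rule, then restriction to variable promoter CpGs
(TSS1500/TSS200/5UTR, overall SD > 0.05).

Expression arrives from one or more bead-array studies; transcripts must
beat twice the study background in at least one sample of every study,
are quantile-normalized within study, and finally mean-centered per
transcript across all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .io_formats import MetharError, PROMOTER_REGIONS

log = logging.getLogger("methar")


class PreconditionError(MetharError):
    pass


class AnnotationError(MetharError):
    pass


@dataclass
class FilterReport:
    """Per-rule removal counts for one filtering pass."""

    input_probes: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    probe_sd: pd.Series | None = None

    def check(self) -> None:
        if sum(self.removed.values()) + self.retained != self.input_probes:
            raise AssertionError("filter report counts do not sum")

    def to_dict(self) -> dict:
        return {"input_probes": self.input_probes, "removed": self.removed,
                "retained": self.retained}


# ---------------------------------------------------------------------------
# BMIQ-style normalization

_GRID = np.linspace(1e-6, 1.0 - 1e-6, 4001)


def _beta_mixture_em(x: np.ndarray, n_states: int = 3, tol: float = 1e-4,
                     max_iter: int = 100) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, bool]:
    """Fit an n-state beta mixture by EM.

    Initialized from quantile cuts at beta < 1/3 (unmethylated) and
    beta > 2/3 (methylated); the M-step recovers each component's beta
    parameters from the responsibility-weighted mean and variance (method
    of moments). Deterministic; returns (a, b, weights, converged).
    """
    x = np.clip(x, 1e-4, 1 - 1e-4)
    cuts = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    resp = np.zeros((len(x), n_states))
    for k in range(n_states):
        resp[:, k] = (x >= cuts[k]) & (x < cuts[k + 1])
    resp[resp.sum(axis=1) == 0, :] = 1.0 / n_states

    a = np.empty(n_states)
    b = np.empty(n_states)
    w = np.empty(n_states)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # M-step (method of moments per component)
        for k in range(n_states):
            wk = resp[:, k]
            tot = wk.sum()
            if tot < 1e-8:
                # empty component: park it at a diffuse beta
                a[k], b[k], w[k] = 1.0, 1.0, 1e-8
                continue
            m = np.average(x, weights=wk)
            v = np.average((x - m) ** 2, weights=wk)
            v = max(v, 1e-6)
            common = max(m * (1 - m) / v - 1.0, 1e-2)
            a[k] = max(m * common, 1e-2)
            b[k] = max((1 - m) * common, 1e-2)
            w[k] = tot / len(x)
        w = w / w.sum()
        # E-step
        dens = np.stack([w[k] * stats.beta.pdf(x, a[k], b[k])
                         for k in range(n_states)], axis=1)
        norm = dens.sum(axis=1)
        norm[norm <= 0] = 1e-300
        resp = dens / norm[:, None]
        ll = np.log(norm).sum()
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(a / (a + b))  # sort states by mean: U, hemi, M
    return a[order], b[order], w[order], converged


def _mixture_cdf(x: np.ndarray, a: np.ndarray, b: np.ndarray,
                 w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for k in range(len(w)):
        out += w[k] * stats.beta.cdf(x, a[k], b[k])
    return out


def bmiq_normalize(beta: pd.DataFrame, annotation: pd.DataFrame,
                   tol: float = 1e-4, max_iter: int = 100,
                   min_probes_per_type: int = 50) -> pd.DataFrame:
    """Map type-II probe betas onto the type-I state distributions.

    Per sample, a 3-state beta mixture is fitted separately to the type-I
    and type-II betas by EM; each type-II value is then quantile-mapped
    through F1^{-1}(F2(beta)), where F2 and F1 are the fitted type-II and
    type-I mixture CDFs. The map is strictly monotone, so the within-sample
    rank order of type-II probes is preserved; type-I probes pass through
    unchanged. Samples whose EM fails to converge are left unnormalized
    with a warning.
    """
    design = annotation.loc[beta.index, "design_type"]
    mask1 = (design == "I").to_numpy()
    mask2 = (design == "II").to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < min_probes_per_type or n2 < min_probes_per_type:
        raise PreconditionError(
            f"need >= {min_probes_per_type} probes of each design type, "
            f"got I={n1}, II={n2}")
    out = beta.copy()
    for sample in beta.columns:
        x1 = beta.loc[mask1, sample].to_numpy()
        x2 = beta.loc[mask2, sample].to_numpy()
        a1, b1, w1, ok1 = _beta_mixture_em(x1, tol=tol, max_iter=max_iter)
        a2, b2, w2, ok2 = _beta_mixture_em(x2, tol=tol, max_iter=max_iter)
        if not (ok1 and ok2):
            log.warning("BMIQ EM did not converge for sample %s; "
                        "leaving it unnormalized", sample)
            continue
        u = _mixture_cdf(np.clip(x2, 1e-6, 1 - 1e-6), a2, b2, w2)
        grid_cdf = _mixture_cdf(_GRID, a1, b1, w1)
        # grid CDF is strictly increasing (mixture density > 0 on (0,1))
        mapped = np.interp(u, grid_cdf, _GRID)
        out.loc[mask2, sample] = np.clip(mapped, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# probe filters


def filter_probes(beta: pd.DataFrame, detp: pd.DataFrame,
                  annotation: pd.DataFrame, p_max: float = 0.05,
                  snp_bp: float = 5.0) -> tuple[pd.DataFrame, FilterReport]:
    """Exclusion-list and detection-p probe filtering.

    Removal rules, applied in order with earlier rules taking precedence in
    the report: cross-reactive probes, meQTL probes, probes closer than
    `snp_bp` base pairs to a known SNP, then probes whose detection p
    exceeds `p_max` in any sample.
    """
    if not beta.index.equals(detp.index) or \
            not beta.columns.equals(detp.columns):
        raise PreconditionError("beta and detection-p axes are not aligned")
    for col in ("cross_reactive", "meqtl", "snp_distance_bp"):
        if col not in annotation.columns:
            raise AnnotationError(f"annotation lacks column {col!r}")
    ann = annotation.loc[beta.index]
    report = FilterReport(input_probes=len(beta))
    alive = pd.Series(True, index=beta.index)

    rules = [
        ("cross_reactive", ann["cross_reactive"].astype(bool)),
        ("meqtl", ann["meqtl"].astype(bool)),
        ("near_snp", ann["snp_distance_bp"] < snp_bp),
        ("detection_p", (detp > p_max).any(axis=1)),
    ]
    for name, hit in rules:
        removed_now = alive & hit
        report.removed[name] = int(removed_now.sum())
        alive &= ~hit
    report.retained = int(alive.sum())
    report.check()
    return beta.loc[alive], report


def promoter_variability_subset(beta: pd.DataFrame,
                                annotation: pd.DataFrame,
                                sd_min: float = 0.05
                                ) -> tuple[pd.DataFrame, FilterReport]:
    """Keep variable promoter CpGs.

    A probe survives if it has at least one gene mapping in
    TSS1500/TSS200/5UTR and its across-sample SD of beta (n-1 denominator)
    is strictly greater than `sd_min`.
    """
    ann = annotation.loc[beta.index]
    is_promoter = ann["gene_region_pairs"].map(
        lambda ps: any(r in PROMOTER_REGIONS for _, r in ps))
    sd = beta.std(axis=1, ddof=1)
    report = FilterReport(input_probes=len(beta), probe_sd=sd)
    report.removed["non_promoter"] = int((~is_promoter).sum())
    keep = is_promoter & (sd > sd_min)
    report.removed["low_sd"] = int((is_promoter & ~(sd > sd_min)).sum())
    report.retained = int(keep.sum())
    report.check()
    return beta.loc[keep], report


# ---------------------------------------------------------------------------
# expression


def filter_expression_probes(raw_expr: pd.DataFrame,
                             background_mean: dict[str, float],
                             groups: dict[str, list[str]],
                             factor: float = 2.0) -> pd.DataFrame:
    """Keep transcripts above `factor` x background in every study.

    A transcript is retained only if, in EACH study group, its signal
    exceeds factor * background_mean[study] in at least one sample of that
    study.
    """
    if set(background_mean) != set(groups):
        raise MetharError("background_mean and groups must name the same "
                          "studies")
    keep = pd.Series(True, index=raw_expr.index)
    for study, samples in groups.items():
        if not samples:
            raise PreconditionError(f"study {study!r} has no samples")
        if background_mean[study] <= 0:
            raise PreconditionError(
                f"study {study!r} background must be positive")
        threshold = factor * background_mean[study]
        keep &= (raw_expr[samples] > threshold).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_expression_probes: dropped %d transcripts below "
                 "background", dropped)
    return raw_expr.loc[keep]


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns.

    Every column's sorted values are replaced by the mean of the sorted
    columns; ties within a column receive the average of the corresponding
    reference quantiles.
    """
    ranks = expr.rank(axis=0, method="average")
    mean_sorted = np.sort(expr.to_numpy(), axis=0).mean(axis=1)
    # interpolate the reference distribution at (possibly fractional) ranks
    positions = np.arange(1, len(expr) + 1, dtype=float)
    out = expr.copy()
    for col in expr.columns:
        out[col] = np.interp(ranks[col].to_numpy(), positions, mean_sorted)
    return out


def quantile_normalize_and_center(expr: pd.DataFrame,
                                  study_groups: dict[str, list[str]]
                                  ) -> pd.DataFrame:
    """Quantile-normalize within each study, then mean-center per transcript
    across all samples."""
    for study, samples in study_groups.items():
        if len(samples) < 2:
            raise PreconditionError(
                f"study {study!r} needs >= 2 samples for quantile "
                "normalization")
    out = expr.copy()
    for samples in study_groups.values():
        out[samples] = quantile_normalize(expr[samples])
    centered = out.sub(out.mean(axis=1), axis=0)
    centered.attrs["centered"] = True
    return centered


def preprocess_methylation(beta: pd.DataFrame, detp: pd.DataFrame,
                           annotation: pd.DataFrame, p_max: float = 0.05,
                           snp_bp: float = 5.0, sd_min: float = 0.05
                           ) -> tuple[pd.DataFrame, dict]:
    """Full methylation flow: BMIQ -> probe filters -> variable promoter
    subset. Returns the final beta matrix and both filter reports."""
    normalized = bmiq_normalize(beta, annotation)
    filtered, rep1 = filter_probes(normalized, detp, annotation,
                                   p_max=p_max, snp_bp=snp_bp)
    final, rep2 = promoter_variability_subset(filtered, annotation,
                                              sd_min=sd_min)
    return final, {"probe_filter": rep1.to_dict(),
                   "promoter_subset": rep2.to_dict()}
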