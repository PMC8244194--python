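"""Statistical layer: rank tests, correlation, FDR, and survival models.

Kaplan-Meier, log-rank, and Cox regression are delegated to lifelines; the
Cox model uses Efron tie handling (metastasis follow-up is recorded in
whole months, so ties are frequent). The median-survival convention is the
smallest time t with S(t) <= 0.5. Cox covariate screening follows a
univariate gate: covariates with univariate p < 0.05 enter the joint model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MetharError

log = logging.getLogger("methar")


class StatsError(MetharError):
    pass


# ---------------------------------------------------------------------------
# elementary tests


def wilcoxon_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided Wilcoxon test.

    Unpaired: rank-sum (Mann-Whitney U statistic); paired: signed-rank.
    Small samples without ties are evaluated by exact enumeration (n <= 25
    per group), larger or tied samples by the tie-corrected normal
    approximation. All-tied data yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise StatsError("paired test requires equal lengths")
    if min(len(x), len(y)) < 3:
        raise StatsError("need n >= 3 per group")
    if paired:
        d = x - y
        if np.all(d == 0):
            log.warning("wilcoxon_test: all paired differences zero; p = 1")
            return 0.0, 1.0
        nz = d[d != 0]
        exact = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
        res = stats.wilcoxon(x, y, zero_method="wilcox",
                             alternative="two-sided",
                             method="exact" if exact else "approx",
                             correction=False)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        log.warning("wilcoxon_test: all values tied; p = 1")
        return float(len(x) * len(y) / 2), 1.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(x), len(y)) <= 25 and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with the t-distribution p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need aligned vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise StatsError("need a 2-D table of nonnegative counts")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise StatsError("an expected cell count is zero; use an exact test")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), int(df), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMCurve:
    """Product-limit curve for one group."""

    group: str
    times: np.ndarray          # event/censoring times in months
    survival: np.ndarray       # S(t) at those times
    at_risk: np.ndarray
    median: float              # smallest t with S(t) <= 0.5; nan if never
    n: int
    n_events: int


def _validate_survival(table: pd.DataFrame) -> None:
    for col in ("months", "event"):
        if col not in table.columns:
            raise StatsError(f"survival table lacks column {col!r}")
    if (table["months"] <= 0).any():
        raise StatsError("months must be > 0")
    if not set(table["event"].unique()) <= {0, 1}:
        raise StatsError("event must be 0/1")


def km_curve(table: pd.DataFrame, group: str) -> dict[str, KMCurve]:
    """Kaplan-Meier curves per level of the `group` column."""
    _validate_survival(table)
    if table[group].isna().any():
        raise StatsError(f"group column {group!r} has missing labels")
    curves: dict[str, KMCurve] = {}
    for label, sub in table.groupby(group, sort=True):
        if len(sub) == 0:
            raise StatsError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["months"], event_observed=sub["event"])
        surv = kmf.survival_function_["KM_estimate"]
        median = kmf.median_survival_time_
        curves[str(label)] = KMCurve(
            group=str(label),
            times=surv.index.to_numpy(dtype=float),
            survival=surv.to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(),
            median=float(median) if np.isfinite(median) else float("nan"),
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return curves


def logrank_test(table: pd.DataFrame, group: str) -> tuple[float, float]:
    """Two-group log-rank test (1 df, hypergeometric variance)."""
    _validate_survival(table)
    levels = [lv for lv in pd.unique(table[group]) if not pd.isna(lv)]
    if len(levels) != 2:
        raise StatsError(f"log-rank needs exactly 2 groups, got {levels}")
    if table["event"].sum() == 0:
        raise StatsError("no events observed")
    a = table[table[group] == levels[0]]
    b = table[table[group] == levels[1]]
    res = _ll_logrank(a["months"], b["months"],
                      event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression with univariate -> multivariate gating


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    model: str     # "univariate" | "multivariate"


def _encode_covariates(table: pd.DataFrame, covariates: list[str],
                       factor_reference: dict[str, str]) -> tuple[
                           pd.DataFrame, dict[str, list[str]]]:
    """Numeric passthrough; categorical covariates reference-coded."""
    cols: dict[str, pd.Series] = {}
    mapping: dict[str, list[str]] = {}
    for cov in covariates:
        series = table[cov]
        if pd.api.types.is_numeric_dtype(series) or \
                pd.api.types.is_bool_dtype(series):
            cols[cov] = series.astype(float)
            mapping[cov] = [cov]
        else:
            levels = sorted(series.dropna().unique())
            ref = factor_reference.get(cov, levels[0])
            if ref not in levels:
                raise StatsError(
                    f"reference level {ref!r} absent from {cov!r}")
            encoded = []
            for level in levels:
                if level == ref:
                    continue
                name = f"{cov}[{level}]"
                cols[name] = (series == level).astype(float)
                encoded.append(name)
            mapping[cov] = encoded
    return pd.DataFrame(cols, index=table.index), mapping


def cox_fit(table: pd.DataFrame, covariates: list[str],
            gate_p: float = 0.05,
            factor_reference: dict[str, str] | None = None
            ) -> tuple[list[CoxResult], list[CoxResult]]:
    """Univariate Cox per covariate, then a multivariate model over the
    covariates whose (minimum, for factors) univariate p is below `gate_p`.

    Categorical covariates are reference-coded (default reference: first
    level in sorted order; override via `factor_reference`, e.g. MetA for
    the metastasis subtype). Efron tie handling throughout.
    """
    _validate_survival(table)
    factor_reference = factor_reference or {}
    if table["event"].sum() < 10:
        log.warning("cox_fit: fewer than 10 events; multivariate estimates "
                    "may be unstable")
    encoded, mapping = _encode_covariates(table, covariates,
                                          factor_reference)

    def _fit(cov_names: list[str], model: str) -> list[CoxResult]:
        data = pd.concat([table[["months", "event"]], encoded[cov_names]],
                         axis=1).dropna()
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="months", event_col="event")
        out = []
        for name in cov_names:
            row = cph.summary.loc[name]
            out.append(CoxResult(
                covariate=name,
                hazard_ratio=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                p=float(row["p"]),
                model=model,
            ))
        return out

    univariate: list[CoxResult] = []
    gate_pass: list[str] = []
    for cov in covariates:
        cov_cols = mapping[cov]
        if not cov_cols:
            continue
        results = _fit(cov_cols, "univariate")
        univariate.extend(results)
        if min(r.p for r in results) < gate_p:
            gate_pass.append(cov)

    multivariate: list[CoxResult] = []
    if gate_pass:
        multi_cols = [c for cov in gate_pass for c in mapping[cov]]
        if len(multi_cols) >= 1:
            multivariate = _fit(multi_cols, "multivariate")
    return univariate, multivariate


def cox_results_frame(results: list[CoxResult]) -> pd.DataFrame:
    """Tabulate Cox results with P / RR / 95% CI columns."""
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "model": [r.model for r in results],
            "P": [r.p for r in results],
            "RR": [r.hazard_ratio for r in results],
            "CI95_low": [r.ci_low for r in results],
            "CI95_high": [r.ci_high for r in results],
        }
    )
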