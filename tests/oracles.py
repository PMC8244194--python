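"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as plain loops / enumeration,
independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def quantile_normalize_oracle(df: pd.DataFrame) -> pd.DataFrame:
    """Rank -> mean-of-sorted-columns lookup, ties averaged."""
    arr = df.to_numpy(dtype=float)
    n, m = arr.shape
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=float)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            # tied block gets the average of its reference quantiles
            value = reference[i:k + 1].mean()
            for idx in order[i:k + 1]:
                out[idx, j] = value
            i = k + 1
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by direct enumeration."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(p[idx] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def silhouette_oracle(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """O(n^2) silhouette widths with s=0 for singletons and a=b=0."""
    n = len(x)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.dist(x[i], x[j])
    widths = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            widths[i] = 0.0
            continue
        a = sum(dist[i, j] for j in same) / len(same)
        b = math.inf
        for lab in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(dist[i, j] for j in others) / len(others))
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook sum-formula Pearson r."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def chi2_oracle(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square statistic and df from the hand formula."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def ranksum_exact_oracle(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration (no ties)."""
    pooled = sorted(x + y)
    nx = len(x)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(rank_of[v] for v in x)
    mean_w = nx * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w):
            count += 1
    return count / total


def dm_oracle(beta: pd.DataFrame, ids1: list[str], ids2: list[str],
              threshold: float) -> dict[str, float]:
    """Per-probe loop: probes with strict |mean1 - mean2| > threshold."""
    out = {}
    for pid in beta.index:
        m1 = sum(beta.at[pid, s] for s in ids1) / len(ids1)
        m2 = sum(beta.at[pid, s] for s in ids2) / len(ids2)
        if abs(m1 - m2) > threshold:
            out[pid] = m1 - m2
    return out


def venn_oracle(tn: set, mn: set, mt: set) -> dict[str, set]:
    """Membership test per element over the union."""
    regions: dict[str, set] = {k: set() for k in
                               ("TN", "MN", "MT", "TN&MN", "TN&MT",
                                "MN&MT", "TN&MN&MT")}
    for item in tn | mn | mt:
        key = "&".join(name for name, group in
                       (("TN", tn), ("MN", mn), ("MT", mt)) if item in group)
        regions[key].add(item)
    return regions


def probe_filter_oracle(annotation: pd.DataFrame, detp: pd.DataFrame,
                        p_max: float, snp_bp: float) -> set[str]:
    """Set-complement of all exclusion rules."""
    keep = set()
    for pid in detp.index:
        row = annotation.loc[pid]
        if row["cross_reactive"] or row["meqtl"]:
            continue
        if row["snp_distance_bp"] < snp_bp:
            continue
        if any(detp.loc[pid, s] > p_max for s in detp.columns):
            continue
        keep.add(pid)
    return keep


def km_survival_oracle(times: np.ndarray, events: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Hand product-limit estimator: S(t) at each distinct event time."""
    order = np.argsort(times)
    times, events = times[order], events[order]
    event_times = sorted(set(times[events == 1]))
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        surv.append(s)
    return np.asarray(event_times, dtype=float), np.asarray(surv)


def pca_t1_eigen_oracle(matrix: np.ndarray) -> np.ndarray:
    """First-PC scores via an explicit covariance eigendecomposition.

    `matrix` is features x samples; returns one score per sample (sign
    arbitrary).
    """
    x = matrix - matrix.mean(axis=1, keepdims=True)
    cov = x @ x.T / (x.shape[1] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v1 = eigvecs[:, np.argmax(eigvals)]
    return v1 @ x
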