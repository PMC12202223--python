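"""Phase-comparison statistics for tilt-test metrics.

Per-patient, per-phase metrics (Ff, FHR, FRR, dFf, Pr) are compared across
a fixed graph of phase pairs: each sub-phase against the immediately
preceding one, plus transient-to-transient and steady-to-steady
comparisons.  Differences are tested with the Wilcoxon signed-rank test
(exact null for small n, normal approximation with continuity and tie
corrections otherwise) under a Bonferroni-corrected threshold
alpha / n_comparisons.  Normality, which decides the summary display form
(mean +/- SD vs median (Q1-Q3)), is assessed with a Monte-Carlo Lilliefors
test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "PHASES",
    "METRICS",
    "ComparisonGraph",
    "lilliefors",
    "wilcoxon_signed_rank",
    "compare_phases",
    "classify_response",
    "summarize",
]

PHASES = ("B1", "B2", "HDT1", "HDT2", "HUT1", "HUT2")
METRICS = ("ff", "fhr", "frr", "delta_ff", "pr")

#: default comparison pairs: consecutive sub-phases, transient-to-transient
#: and steady-to-steady
DEFAULT_PAIRS = [
    ("B1", "B2"), ("B2", "HDT1"), ("HDT1", "HDT2"),
    ("HDT2", "HUT1"), ("HUT1", "HUT2"),
    ("B1", "HDT1"), ("HDT1", "HUT1"),
    ("B2", "HDT2"), ("HDT2", "HUT2"),
]


@dataclass
class ComparisonGraph:
    """Ordered list of phase pairs to compare."""

    pairs: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PAIRS))

    def __post_init__(self):
        for a, b in self.pairs:
            if a not in PHASES or b not in PHASES:
                raise ValueError(f"unknown phase in pair ({a}, {b})")

    def __len__(self) -> int:
        return len(self.pairs)


# --------------------------------------------------------------------------
# Lilliefors normality test with a seeded Monte-Carlo null


_NULL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the standardized sample and N(0, 1), with mean and
    SD estimated from the sample (the Lilliefors composite-null statistic)."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = spstats.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _null_distribution(n: int, n_mc: int, seed: int = 987654321) -> np.ndarray:
    key = (n, n_mc)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed + n)
        samples = rng.standard_normal((n_mc, n))
        z = (samples - samples.mean(axis=1, keepdims=True)) / samples.std(axis=1, ddof=1, keepdims=True)
        z.sort(axis=1)
        cdf = spstats.norm.cdf(z)
        grid = np.arange(1, n + 1) / n
        up = (grid[None, :] - cdf).max(axis=1)
        down = (cdf - (grid[None, :] - 1.0 / n)).max(axis=1)
        _NULL_CACHE[key] = np.maximum(up, down)
    return _NULL_CACHE[key]


def lilliefors(sample: np.ndarray, n_mc: int = 10_000) -> float:
    """Monte-Carlo Lilliefors normality test p-value.

    The null distribution of the statistic (10,000 standard-normal samples
    of the same size, internally seeded) is cached per sample size, so
    repeated calls cost one sort each.  Returns NaN for n < 5 or a
    degenerate (constant) sample.
    """
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        return float("nan")
    if x.std(ddof=1) == 0:
        warnings.warn("degenerate sample (identical values); normality undefined")
        return float("nan")
    d = _lilliefors_statistic(x)
    null = _null_distribution(x.size, n_mc)
    return float((1 + np.sum(null >= d)) / (n_mc + 1))


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  For n <= 15 the exact null is enumerated
    over all 2^n sign patterns (midranks for tied magnitudes); for larger n
    a normal approximation with continuity and tie corrections is used.
    Returns 1.0 (with a warning) when every difference is zero, NaN when
    fewer than 5 non-zero differences remain.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    n = d.size
    if n < 5:
        warnings.warn("fewer than 5 non-zero differences; p missing")
        return float("nan")
    ranks = spstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 15:
        # all sign patterns via the bit matrix
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1)
        w_null = signs @ ranks
        cnt_le = int(np.sum(w_null <= w_plus + 1e-9))
        cnt_ge = int(np.sum(w_null >= w_plus - 1e-9))
        return float(min(1.0, 2.0 * min(cnt_le, cnt_ge) / 2 ** n))
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if diff != 0 else 0.0
    return float(2.0 * spstats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# comparisons, classification, summary


def compare_phases(metrics: pd.DataFrame, graph: ComparisonGraph | None = None,
                   alpha: float = 0.05,
                   metric_names: tuple[str, ...] = ("ff", "fhr", "delta_ff", "pr"),
                   ) -> pd.DataFrame:
    """Pairwise phase comparisons with Bonferroni correction.

    ``metrics`` is long-form with columns ``patient``, ``phase`` and the
    metric columns.  For each metric and pair the paired Wilcoxon test is
    run on patients with both phases present; significance threshold is
    ``alpha / len(graph)``.
    """
    graph = graph or ComparisonGraph()
    thr = alpha / len(graph)
    rows = []
    for metric in metric_names:
        if metric not in metrics.columns:
            continue
        wide = metrics.pivot_table(index="patient", columns="phase", values=metric,
                                   aggfunc="first")
        for a, b in graph.pairs:
            row = {"metric": metric, "phase_a": a, "phase_b": b,
                   "threshold": thr}
            if a not in wide.columns or b not in wide.columns:
                row.update(n=0, median_diff=np.nan, p=np.nan,
                           significant=False, evaluable=False)
                rows.append(row)
                continue
            paired = wide[[a, b]].dropna()
            n = len(paired)
            if n < 5:
                row.update(n=n, median_diff=np.nan, p=np.nan,
                           significant=False, evaluable=False)
            else:
                p = wilcoxon_signed_rank(paired[b].to_numpy(), paired[a].to_numpy())
                row.update(
                    n=n,
                    median_diff=float((paired[b] - paired[a]).median()),
                    p=p,
                    significant=bool(not np.isnan(p) and p < thr),
                    evaluable=True,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def classify_response(current: float, previous: float,
                      cohort_median: float | None = None) -> str:
    """Classify a phase-to-phase change as increase / decrease / minimal.

    Minimal means a relative change below 1% of the previous value; when the
    previous value is zero the absolute change is judged against 1% of the
    cohort median instead.
    """
    if np.isnan(current) or np.isnan(previous):
        raise ValueError("both values must be present")
    if previous == 0:
        warnings.warn("previous value is zero; classifying by absolute change "
                      "against 1% of the cohort median")
        scale = abs(cohort_median) if cohort_median else 1.0
        if abs(current - previous) < 0.01 * scale:
            return "minimal"
        return "increase" if current > previous else "decrease"
    if abs(current - previous) / abs(previous) < 0.01:
        return "minimal"
    return "increase" if current > previous else "decrease"


def summarize(metrics: pd.DataFrame, alpha: float = 0.05,
              metric_names: tuple[str, ...] = METRICS) -> pd.DataFrame:
    """Per metric x phase summary in the conventional clinical display form.

    The Lilliefors test decides the form per cell: mean +/- SD for samples
    compatible with normality, median (Q1-Q3) otherwise (linear-interpolation
    quartiles).
    """
    rows = []
    for metric in metric_names:
        if metric not in metrics.columns:
            continue
        for phase in PHASES:
            vals = metrics.loc[metrics["phase"] == phase, metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            p_norm = lilliefors(vals)
            gaussian = bool(not np.isnan(p_norm) and p_norm >= alpha)
            if gaussian:
                disp = f"{vals.mean():.3g} ± {vals.std(ddof=1):.3g}"
            else:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                disp = f"{med:.3g} ({q1:.3g}−{q3:.3g})"
            rows.append({
                "metric": metric, "phase": phase, "n": int(vals.size),
                "gaussian": gaussian, "lilliefors_p": p_norm,
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "display": disp,
            })
    return pd.DataFrame(rows)


def wilcoxon_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Independent enumeration oracle for the exact Wilcoxon p-value.

    Walks every sign pattern with itertools (no vectorized shortcuts), for
    cross-checking the fast path on small n.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = spstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    cnt_le = cnt_ge = 0
    for pattern in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, pattern) if s)
        if w <= w_obs + 1e-9:
            cnt_le += 1
        if w >= w_obs - 1e-9:
            cnt_ge += 1
    return min(1.0, 2.0 * min(cnt_le, cnt_ge) / 2 ** n)
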