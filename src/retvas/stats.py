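"""Paired device-agreement statistics.

Agreement between the reference and handheld arms is quantified per metric by
Bland–Altman analysis: the mean paired difference (reference − handheld) and
limits of agreement at ±1.96 standard deviations of the differences.  The
Bradley–Blackwood F-test (regression of differences on means) jointly tests
equal means and equal variances; a separate regression of differences on sums
tests for proportional bias.  Edge-length distributions are compared with the
two-sample Kolmogorov–Smirnov test; categorical evaluability outcomes with a
conditional exact Fisher test, an exact McNemar test on discordant pairs, and
a pooled two-sample test of proportions.

All p-values are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlandAltmanResult",
    "AgreementReport",
    "bland_altman",
    "bradley_blackwood",
    "slope_test",
    "ks_two_sample",
    "fisher_exact",
    "mcnemar_exact",
    "two_proportion_test",
    "compare_metrics",
]

DEFAULT_ALPHA = 0.05
LOA_FACTOR = 1.96  # limits of agreement: mean ± 1.96 sd of the differences

METRIC_COLUMNS = ("density_pct", "n_external", "n_internal", "n_edges", "fd")
METRIC_LABELS = {
    "density_pct": "vessel density",
    "n_external": "external nodes",
    "n_internal": "internal nodes",
    "n_edges": "edges",
    "fd": "fractal dimension",
}


@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bb_F: float = float("nan")
    bb_p: float = float("nan")
    slope: float = float("nan")
    slope_p: float = float("nan")


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    return a, b


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements (difference a − b)."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        n=a.size,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_FACTOR * sd,
        loa_high=mean + LOA_FACTOR * sd,
    )


def bradley_blackwood(a, b) -> tuple[float, float]:
    """Bradley–Blackwood joint test of equal means and equal variances.

    Regresses d = a − b on m = (a + b)/2 and tests intercept = slope = 0:
    ``F = [(Σd² − SSE)/2] / [SSE/(n−2)]`` on (2, n−2) degrees of freedom.
    When the arms agree exactly (d ≡ 0) there is no disagreement to test and
    (0, 1) is returned by convention.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0
    m = (a + b) / 2.0
    if np.ptp(m) == 0:
        raise ValueError("all pair means identical; regression undefined")
    slope, intercept = np.polyfit(m, d, 1)
    sse = float(np.sum((d - (intercept + slope * m)) ** 2))
    ssd = float(np.sum(d**2))
    if sse <= 0:
        return float("inf"), 0.0
    F = ((ssd - sse) / 2.0) / (sse / (n - 2))
    p = float(sps.f.sf(F, 2, n - 2))
    return float(F), p


def slope_test(a, b) -> tuple[float, float]:
    """OLS regression of differences on sums; two-sided t-test on the slope."""
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    s = a + b
    if np.ptp(s) == 0:
        raise ValueError("sums have zero variance")
    res = sps.linregress(s, a - b)
    return float(res.slope), float(res.pvalue)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (exact for small samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def _table_prob(table: np.ndarray, row_sums, col_sums, n: int) -> float:
    """Conditional probability of an r×c table given its margins."""
    logp = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(n + 1)
        - sum(math.lgamma(v + 1) for v in table.ravel())
    )
    return math.exp(logp)


def _iter_tables(row_sums, col_sums):
    """Enumerate all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rows(remaining_cols, i):
        if i == r - 1:
            row = tuple(remaining_cols)
            if all(v >= 0 for v in row) and sum(row) == row_sums[i]:
                yield (row,)
            return
        for row in _compositions(row_sums[i], remaining_cols):
            rest = [rc - v for rc, v in zip(remaining_cols, row)]
            for tail in rows(rest, i + 1):
                yield (row,) + tail

    yield from rows(list(col_sums), 0)


def _compositions(total, caps):
    """All tuples of len(caps) non-negative ints summing to total, v_j <= caps[j]."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    for v in range(min(total, caps[0]) + 1):
        for tail in _compositions(total - v, caps[1:]):
            yield (v,) + tail


def fisher_exact(table) -> float:
    """Conditional exact Fisher test for an r×c table (r, c ≤ 3), two-sided.

    The p-value sums the conditional probabilities (fixed margins) of every
    table no more probable than the observed one.  Any zero margin leaves a
    degenerate conditional distribution and p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] > 3 or t.shape[1] > 3:
        raise ValueError("table must be 2-D with at most 3 rows and 3 columns")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or (row_sums == 0).any() or (col_sums == 0).any():
        return 1.0
    p_obs = _table_prob(t, row_sums, col_sums, n)
    p = 0.0
    for cand in _iter_tables(tuple(row_sums), tuple(col_sums)):
        pc = _table_prob(np.asarray(cand), row_sums, col_sums, n)
        if pc <= p_obs * (1 + 1e-9):
            p += pc
    return float(min(p, 1.0))


def mcnemar_exact(n01: int, n10: int) -> float:
    """Exact McNemar test on discordant pair counts (two-sided binomial)."""
    if n01 < 0 or n10 < 0:
        raise ValueError("counts must be non-negative")
    n = n01 + n10
    if n == 0:
        return 1.0
    k = min(n01, n10)
    return float(min(1.0, 2.0 * sps.binom.cdf(k, n, 0.5)))


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float, float, float]:
    """Pooled two-sample z-test of proportions; returns (p1, p2, z, p)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p = float(2 * sps.norm.sf(abs(z)))
    return float(p1), float(p2), float(z), p


# ---------------------------------------------------------------------------
# study-level comparison
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-metric agreement table across strata, plus KS edge-length tests."""

    table: pd.DataFrame  # rows: metric × stratum
    ks: dict  # stratum -> (D, p) on pooled edge lengths
    plot_data: pd.DataFrame  # per-eye (metric, stratum, mean, diff)
    strata: dict = field(default_factory=dict)  # stratum -> n pairs


def compare_metrics(
    metric_table: pd.DataFrame,
    curated_index: list[int] | None = None,
    edge_lengths: dict | None = None,
    min_pairs: int = 3,
) -> AgreementReport:
    """Bland–Altman agreement per metric, for all pairs and the curated subset.

    ``metric_table`` holds one row per (eye_id, arm) with the metric columns
    ``density_pct, n_external, n_internal, n_edges, fd``; arms are labelled
    ``reference`` and ``handheld`` and differences are reference − handheld.
    ``edge_lengths`` optionally maps arm -> eye_id -> length array for the
    pooled KS comparison (each image contributing its normalized lengths).
    Strata smaller than ``min_pairs`` are skipped with a warning.
    """
    wide = metric_table.pivot(index="eye_id", columns="arm", values=list(METRIC_COLUMNS))
    eyes = list(wide.index)
    strata: dict[str, list] = {"unsupervised": eyes}
    if curated_index is not None:
        strata["curated"] = [eyes[i] for i in curated_index]

    rows, plot_rows, ks_out, sizes = [], [], {}, {}
    for stratum, idx in strata.items():
        sizes[stratum] = len(idx)
        if len(idx) < min_pairs:
            warnings.warn(f"stratum {stratum!r} has {len(idx)} pairs (< {min_pairs}); skipped",
                          stacklevel=2)
            continue
        for col in METRIC_COLUMNS:
            a = wide.loc[idx, (col, "reference")].to_numpy(dtype=float)
            b = wide.loc[idx, (col, "handheld")].to_numpy(dtype=float)
            ba = bland_altman(a, b)
            try:
                ba.bb_F, ba.bb_p = bradley_blackwood(a, b)
            except ValueError:
                pass
            try:
                ba.slope, ba.slope_p = slope_test(a, b)
            except ValueError:
                pass
            rows.append(
                {
                    "metric": METRIC_LABELS[col],
                    "stratum": stratum,
                    "n": ba.n,
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "p_joint": ba.bb_p,
                    "p_slope": ba.slope_p,
                }
            )
            for eye, ai, bi in zip(idx, a, b):
                plot_rows.append(
                    {"metric": METRIC_LABELS[col], "stratum": stratum,
                     "eye_id": eye, "mean": (ai + bi) / 2, "diff": ai - bi}
                )
        if edge_lengths is not None:
            pooled = {}
            for arm in ("reference", "handheld"):
                per_eye = [np.asarray(edge_lengths[arm][e], dtype=float) for e in idx
                           if e in edge_lengths.get(arm, {})]
                per_eye = [v for v in per_eye if v.size]
                pooled[arm] = np.concatenate(per_eye) if per_eye else np.array([])
            if pooled["reference"].size and pooled["handheld"].size:
                ks_out[stratum] = ks_two_sample(pooled["reference"], pooled["handheld"])

    return AgreementReport(
        table=pd.DataFrame(rows),
        ks=ks_out,
        plot_data=pd.DataFrame(plot_rows),
        strata=sizes,
    )
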