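"""Two-group statistical comparison of sleep metrics.

Implements the comparison protocol used for the cohort analysis: independent
two-sample t tests per metric (pooled-variance by default, Welch optional),
percentile bootstrap confidence intervals (1000 resamples), relative-change
summaries, and a comparison table with the difference reported as
sham - exposed. No multiple-testing correction is applied by default
(a Holm adjustment is available), alpha = 0.05.

Percentage-valued metrics are additionally exported as proportion
differences (divided by 100, three decimals) to mirror the conventional
table formatting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .exceptions import DataError, UndefinedMetricError
from .metrics import METRIC_COLUMNS

__all__ = ["TTestResult", "two_sample_t", "paired_t", "bootstrap_ci",
           "relative_change", "compare_cohorts", "table_export"]

#: Sentinel for an infinite t statistic (zero-variance paired differences).
T_INF = float("inf")


@dataclass
class TTestResult:
    t: float
    p: float
    ci_low: float
    ci_high: float
    df: float


def two_sample_t(a, b, equal_var: bool = True,
                 confidence: float = 0.95) -> TTestResult:
    """Independent two-sample t test of mean(a) - mean(b).

    Pooled-variance by default; ``equal_var=False`` gives the Welch form.
    Returns the t statistic, two-sided p, and the CI on the mean difference.
    Two zero-variance samples with equal means give t = 0, p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        d = a.mean() - b.mean()
        if d == 0:
            return TTestResult(0.0, 1.0, 0.0, 0.0, a.size + b.size - 2)
        return TTestResult(np.sign(d) * T_INF, 0.0, d, d, a.size + b.size - 2)
    res = sst.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(confidence)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(ci.low), float(ci.high), float(res.df))


def paired_t(a, b) -> TTestResult:
    """Paired t test (one-sample t on the differences), two-sided.

    A constant non-zero difference (zero variance) returns the infinite-t
    sentinel with p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise DataError("paired samples must have equal length")
    if a.size < 2:
        raise DataError("need n >= 2 pairs")
    d = a - b
    if np.var(d) == 0:
        if d[0] == 0:
            return TTestResult(0.0, 1.0, 0.0, 0.0, a.size - 1)
        return TTestResult(np.sign(d[0]) * T_INF, 0.0,
                           float(d[0]), float(d[0]), a.size - 1)
    res = sst.ttest_rel(a, b)
    ci = res.confidence_interval(0.95)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(ci.low), float(ci.high), float(res.df))


def bootstrap_ci(a, b, n_boot: int = 1000, statistic=None,
                 seed: int = 0, confidence: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI of statistic(a, b) (default mean(a) - mean(b)).

    Resampling is with replacement within each group; seeded, reproducible.
    """
    if n_boot < 100:
        raise DataError("need at least 100 bootstrap samples")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = np.random.default_rng(seed)
    if statistic is None:
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        stats = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    else:
        stats = np.array([
            statistic(a[rng.integers(0, a.size, a.size)],
                      b[rng.integers(0, b.size, b.size)])
            for _ in range(n_boot)])
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def relative_change(exposed_mean: float, sham_mean: float,
                    direction: str) -> float:
    """Percent change of the exposed group relative to sham.

    direction="decrease": (sham - exposed) / sham x 100;
    direction="increase": (exposed - sham) / sham x 100.
    """
    if sham_mean == 0:
        raise UndefinedMetricError("relative change undefined: sham mean is 0")
    if direction == "decrease":
        return 100.0 * (sham_mean - exposed_mean) / sham_mean
    if direction == "increase":
        return 100.0 * (exposed_mean - sham_mean) / sham_mean
    raise DataError(f"direction must be 'increase' or 'decrease', got {direction!r}")


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_cohorts(exposed: pd.DataFrame, sham: pd.DataFrame,
                    metrics: list[str] | None = None,
                    equal_var: bool = True, n_boot: int = 1000,
                    seed: int = 0, alpha: float = 0.05,
                    holm: bool = False) -> pd.DataFrame:
    """Per-metric comparison table of two cohorts of sleep metrics.

    ``exposed`` / ``sham`` are per-subject metric tables (columns named as
    in :data:`~somnostage.metrics.METRIC_COLUMNS`). The difference column is
    sham - exposed. Nights with an undefined metric (NaN) are dropped for
    that metric with a note in the ``n_exposed``/``n_sham`` columns.
    """
    if len(exposed) == 0 or len(sham) == 0:
        raise DataError("both groups must be non-empty")
    metrics = metrics or [m for m in METRIC_COLUMNS
                          if m in exposed.columns and m in sham.columns]
    rows = []
    for i, m in enumerate(metrics):
        a = exposed[m].dropna().to_numpy(float)
        b = sham[m].dropna().to_numpy(float)
        # the t test and CI follow the table's sham - exposed direction
        res = two_sample_t(b, a, equal_var=equal_var)
        blo, bhi = bootstrap_ci(b, a, n_boot=n_boot, seed=seed + i)
        rows.append({
            "metric": m,
            "exposed_mean": a.mean(), "exposed_sd": a.std(ddof=1),
            "sham_mean": b.mean(), "sham_sd": b.std(ddof=1),
            "difference": b.mean() - a.mean(),
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "boot_ci_low": blo, "boot_ci_high": bhi,
            "t": res.t, "p": res.p,
            "n_exposed": a.size, "n_sham": b.size,
        })
    df = pd.DataFrame(rows)
    if holm:
        df["p_adj"] = _holm(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df


def table_export(comparison: pd.DataFrame) -> pd.DataFrame:
    """Publication-style formatting of a comparison table.

    Percentage metrics report the difference and its CI as proportions
    (divided by 100) at three decimals; other metrics at two decimals.
    """
    out = []
    for _, r in comparison.iterrows():
        is_pct = str(r["metric"]).endswith("%")
        scale = 100.0 if is_pct else 1.0
        nd = 3 if is_pct else 2
        out.append({
            "metric": r["metric"],
            "exposed": f"{r['exposed_mean']:.2f} ± {r['exposed_sd']:.1f}",
            "sham": f"{r['sham_mean']:.2f} ± {r['sham_sd']:.1f}",
            "difference": round(r["difference"] / scale, nd),
            "ci": f"({r['ci_low'] / scale:.{nd}g}, {r['ci_high'] / scale:.{nd}g})",
            "t": round(r["t"], 2),
            "p": "<0.001" if r["p"] < 0.001 else round(r["p"], 3),
        })
    return pd.DataFrame(out)
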