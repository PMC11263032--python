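"""Cohort-level cross-metric comparison.

Counts of patients with a significant 24-h cycle per metric, group PLV as
mean +- SD of per-patient values, and the pairwise inter-metric Pearson
correlation matrix: per patient, hourly series of two metrics are
correlated over their shared non-missing hours, then per-patient r values
are averaged across the cohort; group significance of the mean r against
zero uses a one-sample t-test on Fisher-z transformed values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import HourlySeries

MIN_SHARED_HOURS = 48


def metric_correlation(a: HourlySeries, b: HourlySeries,
                       min_hours: int = MIN_SHARED_HOURS) -> float:
    """Pearson r of two hourly series on their shared non-missing hours.

    NaN when fewer than ``min_hours`` hours are shared or either series is
    constant on them.
    """
    n = min(a.n_hours, b.n_hours)
    ok = ~a.missing[:n] & ~b.missing[:n]
    if ok.sum() < min_hours:
        return float("nan")
    x, y = a.values[:n][ok], b.values[:n][ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def correlation_matrix(hourly: dict, metrics: list[str]):
    """Cohort-mean correlation matrix and its significance stars.

    ``hourly`` maps (patient_id, metric) -> HourlySeries.  Returns
    ``(mean_r, stars)`` DataFrames indexed by metric.  Significance per
    pair: one-sample t-test of per-patient Fisher-z r against zero.
    """
    patients = sorted({p for (p, _) in hourly})
    mean_r = pd.DataFrame(np.eye(len(metrics)), index=metrics, columns=metrics)
    stars = pd.DataFrame("", index=metrics, columns=metrics)
    for i, mi in enumerate(metrics):
        for j in range(i + 1, len(metrics)):
            mj = metrics[j]
            rs = []
            for p in patients:
                if (p, mi) in hourly and (p, mj) in hourly:
                    r = metric_correlation(hourly[(p, mi)], hourly[(p, mj)])
                    if np.isfinite(r):
                        rs.append(r)
            if not rs:
                mean_r.loc[mi, mj] = mean_r.loc[mj, mi] = np.nan
                continue
            rs = np.clip(np.asarray(rs), -0.999999, 0.999999)
            mean_r.loc[mi, mj] = mean_r.loc[mj, mi] = float(np.mean(rs))
            if len(rs) >= 3 and np.std(rs) > 0:
                t = stats.ttest_1samp(np.arctanh(rs), 0.0)
                stars.loc[mi, mj] = stars.loc[mj, mi] = _stars(float(t.pvalue))
    return mean_r, stars


def summarize_cohort(results: pd.DataFrame, hourly: dict | None = None):
    """Cohort table: cycle counts, group PLV, and the correlation matrix.

    ``results`` is the tidy frame from :func:`ictalcycles.pipeline.run_cohort`.
    Returns a dict with ``cycle_counts`` (per-metric n significant /
    fraction), ``plv_summary`` (mean, sd, n), and, when ``hourly`` is
    given, ``correlations`` and ``correlation_stars``.
    """
    if results.empty:
        raise ValueError("empty cohort")
    metrics = list(results.metric.unique())
    n_pat = results.patient_id.nunique()
    cyc = (results.groupby("metric").significant.sum().reindex(metrics)
           .rename("n_significant").to_frame())
    cyc["n_patients"] = n_pat
    cyc["fraction"] = cyc.n_significant / n_pat
    plv_rows = {}
    for m, grp in results.groupby("metric"):
        v = grp.plv.dropna()
        plv_rows[m] = dict(mean=v.mean() if len(v) else np.nan,
                           sd=v.std(ddof=1) if len(v) > 1 else np.nan,
                           n=len(v))
    out = {"cycle_counts": cyc,
           "plv_summary": pd.DataFrame(plv_rows).T.reindex(metrics)}
    if hourly is not None:
        mean_r, stars = correlation_matrix(hourly, metrics)
        out["correlations"] = mean_r
        out["correlation_stars"] = stars
    return out
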