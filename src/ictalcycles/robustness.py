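"""Degradation of cycle detection and PLV under spatial/temporal subsampling.

Spatial subsampling fixes a random electrode subset per patient for the
whole record (an implant's montage is fixed); temporal subsampling redraws
the retained 2-min windows independently each hour (a duty-cycled recorder
samples every hour).  Spatial subsampling applies to the univariate
metrics only (IEDF, TCM, VM); the network metrics (NS, SCM) are defined
across the full montage.  The fraction label "s" denotes the single-unit
level: one electrode, or one 2-min window per hour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import UNIVARIATE_METRICS
from .pipeline import patient_cycle, patient_hourly, patient_plv
from .synth import PatientWindows

SINGLE = "s"


@dataclass
class SubsampleSpec:
    """One subsampling experiment: axis, fraction levels, repeats."""

    axis: str                          # "spatial" | "temporal"
    fractions: Sequence[float | str] = (1.0, 0.5, 0.2, 0.1, SINGLE)
    n_repeats: int = 20
    seed: int = 0
    channel_pool: str = "default"      # IEDF spatial: "soz" | "all" | "non_soz"

    def __post_init__(self) -> None:
        if self.axis not in ("spatial", "temporal"):
            raise ValueError("axis must be 'spatial' or 'temporal'")


def _n_keep(fraction, total: int) -> int:
    if fraction == SINGLE:
        return 1
    f = float(fraction)
    if not 0 < f <= 1:
        raise ValueError(f"fraction must be in (0, 1] or 's', got {fraction}")
    return max(1, int(round(f * total)))


def spatial_subset(pw: PatientWindows, metric: str, fraction,
                   rng: np.random.Generator, channel_pool: str = "default") -> np.ndarray:
    """Fixed random electrode subset (boolean mask over channels).

    For IEDF the pool defaults to SOZ channels (discharges concentrate
    there); ``channel_pool='all'`` or ``'non_soz'`` reproduce the
    degradation seen when subsampling may or must omit the SOZ.
    """
    n_ch = pw.values[metric].shape[1]
    if metric == "IEDF":
        pool_name = "soz" if channel_pool == "default" else channel_pool
        pool = {"soz": np.flatnonzero(pw.soz_mask),
                "all": np.arange(n_ch),
                "non_soz": np.flatnonzero(~pw.soz_mask)}[pool_name]
    else:
        pool = np.arange(n_ch)
    k = _n_keep(fraction, len(pool))
    chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
    mask = np.zeros(n_ch, dtype=bool)
    mask[chosen] = True
    return mask


def temporal_subset(pw: PatientWindows, fraction,
                    rng: np.random.Generator) -> np.ndarray:
    """Fresh per-hour draw of retained windows (boolean mask over windows)."""
    grid = pw.grid
    keep = np.zeros(len(grid.windows), dtype=bool)
    for h in range(grid.n_hours):
        idx = np.flatnonzero((grid.hour_index == h) & grid.usable)
        if idx.size == 0:
            continue
        k = _n_keep(fraction, idx.size)
        keep[rng.choice(idx, size=min(k, idx.size), replace=False)] = True
    return keep


def subsample_run(cohort: list[PatientWindows], metric: str,
                  spec: SubsampleSpec, n_sim: int = 2000) -> pd.DataFrame:
    """Re-run cycle detection and PLV at every subsampling level.

    Returns a long-format frame with columns metric, axis, fraction,
    repeat, patient_id, p24, significant, plv.  Fraction 1.0 (the full
    sampling reference) is deterministic, so it is evaluated once per
    patient regardless of ``n_repeats``.
    """
    if spec.axis == "spatial" and metric not in UNIVARIATE_METRICS:
        raise ValueError(
            f"spatial subsampling is undefined for the network metric {metric}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for fraction in spec.fractions:
        full = (fraction == 1.0)
        for rep in range(1 if full else spec.n_repeats):
            for pw in cohort:
                ch_mask = win_mask = None
                if not full:
                    if spec.axis == "spatial":
                        ch_mask = spatial_subset(pw, metric, fraction, rng,
                                                 spec.channel_pool)
                    else:
                        win_mask = temporal_subset(pw, fraction, rng)
                elif pw.values[metric].ndim == 2 and metric == "IEDF":
                    ch_mask = pw.soz_mask  # reference IEDF is SOZ-restricted
                hs = patient_hourly(pw, metric, channel_subset=ch_mask,
                                    window_subset=win_mask)
                cyc = patient_cycle(hs, n_sim=n_sim, rng=rng)
                pv, _ = patient_plv(hs, pw.seizure_onsets_s)
                rows.append(dict(metric=metric, axis=spec.axis,
                                 fraction=str(fraction), repeat=rep,
                                 patient_id=pw.patient_id, p24=cyc.p24,
                                 significant=cyc.significant, plv=pv))
    return pd.DataFrame(rows)


def compare_to_reference(result: pd.DataFrame, value: str = "plv",
                         reference_fraction: str = "1.0",
                         test: str = "wilcoxon") -> pd.DataFrame:
    """Paired test of each subsampling level against full sampling.

    Per-patient values are averaged over repeats, then compared with a
    two-sided paired Wilcoxon signed-rank test (or paired t-test).  Levels
    identical to the reference give p = 1; fewer than 6 paired patients
    skip the test (p = NaN, flagged).
    """
    ref = (result[result.fraction == reference_fraction]
           .groupby("patient_id")[value].mean())
    rows = []
    for fraction, grp in result.groupby("fraction"):
        if fraction == reference_fraction:
            continue
        cur = grp.groupby("patient_id")[value].mean()
        common = ref.index.intersection(cur.index)
        a, b = ref.loc[common].to_numpy(), cur.loc[common].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 6:
            rows.append(dict(fraction=fraction, n=len(a), p_value=np.nan,
                             skipped=True))
            continue
        d = b - a
        if np.allclose(d, 0):
            p = 1.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(a, b).pvalue)
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
        rows.append(dict(fraction=fraction, n=len(a), p_value=p, skipped=False))
    out = pd.DataFrame(rows)
    if len(out):
        out["stars"] = out.p_value.map(
            lambda p: "***" if p < 0.001 else "**" if p < 0.01
            else "*" if p < 0.05 else "")
    return out
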