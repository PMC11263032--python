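"""Per-patient pipeline glue: recordings or synthetic window values ->
hourly series -> cycle test and seizure phase locking; cohort runs
collected into tidy DataFrames."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cycles import CycleResult, clean_series, detect_cycle
from .metrics import (METRICS, HourlySeries, aggregate_hourly, build_window_grid,
                      count_ieds, ns_metric, scm_metric, tcm_metric, variance_metric)
from .phase import cdf_reference, cycle_phase, plv, seizure_phases
from .preprocess import band_filter, downsample_to, normalize_hour, power_fluctuations
from .recording import Recording
from .synth import PatientWindows


def compute_patient_windows(rec: Recording, metrics: tuple[str, ...] = METRICS,
                            windows_per_hour: int | None = None,
                            classifier=None, patient_id: int = 0,
                            normalize_hourly: bool = False) -> PatientWindows:
    """All requested window metrics for one (preprocessed) recording.

    Expects the base filter chain already applied and fs = 256 Hz.  Band
    routing follows the defaults: VM on the broadband signal, NS on the
    gamma-filtered signal, TCM and SCM on the gamma log-power series, IEDF
    on a 200 Hz resample (the candidate detector's native rate).

    ``normalize_hourly`` z-scores each channel per hour first; off by
    default because per-hour unit variance would flatten exactly the
    between-hour variance signal the VM tracks.
    """
    if normalize_hourly:
        sig = rec.signal.copy()
        for h0, h1 in rec.hour_boundaries:
            i0, i1 = int(round(h0 * rec.fs)), int(round(h1 * rec.fs))
            sig[:, i0:i1], _ = normalize_hour(sig[:, i0:i1])
        rec = rec.with_signal(sig)
    grid = build_window_grid(rec.hour_boundaries, rec.seizures,
                             windows_per_hour=windows_per_hour)
    need = set(metrics)
    broadband = band_filter(rec, "broadband").signal if "VM" in need else None
    gamma = band_filter(rec, "gamma").signal if "NS" in need else None
    power = (power_fluctuations(rec, "gamma").values
             if need & {"TCM", "SCM"} else None)
    rec200 = downsample_to(rec, 200.0) if "IEDF" in need else None

    n_w = len(grid.windows)
    values: dict[str, np.ndarray] = {
        m: np.empty((n_w, rec.n_channels)) if m in ("VM", "TCM", "IEDF")
        else np.empty(n_w) for m in need}
    for i, (t0, t1) in enumerate(grid.windows):
        if "VM" in need:
            values["VM"][i] = variance_metric(
                broadband[:, int(t0 * rec.fs): int(t1 * rec.fs)])
        if "NS" in need:
            values["NS"][i] = ns_metric(
                gamma[:, int(t0 * rec.fs): int(t1 * rec.fs)])
        if power is not None:
            f0, f1 = int(t0 * 8), int(t1 * 8)
            if "TCM" in need:
                values["TCM"][i] = tcm_metric(power[:, f0:f1])
            if "SCM" in need:
                values["SCM"][i] = scm_metric(power[:, f0:f1], rec.electrode_xyz)
        if "IEDF" in need:
            j0, j1 = int(t0 * 200), int(t1 * 200)
            counts = count_ieds(rec200.signal[:, j0:j1], 200.0, classifier)
            values["IEDF"][i] = counts / (grid.window_len / 60.0)
    hour_of_day = (rec.start_time.hour
                   + (rec.hour_boundaries[:, 0] // 3600).astype(int)) % 24
    return PatientWindows(patient_id=patient_id, grid=grid,
                          hour_of_day=hour_of_day, values=values,
                          soz_mask=rec.soz_mask, electrode_xyz=rec.electrode_xyz,
                          seizure_onsets_s=rec.seizures[:, 0] if rec.seizures.size else np.empty(0),
                          truth=None)


def patient_hourly(pw: PatientWindows, metric: str,
                   channel_subset: np.ndarray | None = None,
                   window_subset: np.ndarray | None = None) -> HourlySeries:
    """Hourly series of one metric for one patient (optionally subsampled)."""
    return aggregate_hourly(pw.values[metric], pw.grid,
                            hour_of_day=pw.hour_of_day,
                            channel_subset=channel_subset,
                            window_subset=window_subset, metric=metric)


def patient_cycle(hourly: HourlySeries, n_sim: int = 10_000,
                  rng: np.random.Generator | int | None = None,
                  period_h: float = 24.0) -> CycleResult:
    return detect_cycle(hourly.values, hourly.missing, period_h=period_h,
                        n_sim=n_sim, rng=rng)


def patient_plv(hourly: HourlySeries, seizure_onsets_s: np.ndarray) -> tuple[float, int]:
    """PLV of seizures to the metric's 2-30 h cycle phase.

    Returns ``(plv, n_seizures_used)``; NaN PLV for degenerate series.
    """
    try:
        cleaned = clean_series(hourly.values, hourly.missing, min_hours=60)
    except ValueError:
        return float("nan"), 0
    if cleaned.std() == 0:
        return float("nan"), 0
    phases = cycle_phase(cleaned)
    ph, _ = seizure_phases(phases, seizure_onsets_s)
    if ph.size == 0:
        return float("nan"), 0
    return plv(ph), int(ph.size)


def run_cohort(cohort: list[PatientWindows], metrics: tuple[str, ...],
               n_sim: int = 10_000,
               rng: np.random.Generator | int | None = None,
               include_cdf: bool = True):
    """Cycle test + PLV for every patient and metric.

    Returns ``(results, hourly)``: a tidy DataFrame with columns
    patient_id, metric, p24, significant, alpha_hat, plv, n_seizures, and
    a dict (patient_id, metric) -> HourlySeries for correlation analyses.
    The clock reference CDF is appended as a pseudo-metric.
    """
    rng = np.random.default_rng(rng)
    rows = []
    hourly_store: dict[tuple[int, str], HourlySeries] = {}
    for pw in cohort:
        per_metric = {m: patient_hourly(pw, m) for m in metrics}
        if include_cdf:
            per_metric["CDF"] = cdf_reference(pw.hour_of_day)
        for m, hs in per_metric.items():
            hourly_store[(pw.patient_id, m)] = hs
            cyc = patient_cycle(hs, n_sim=n_sim, rng=rng)
            pv, n_sz = patient_plv(hs, pw.seizure_onsets_s)
            rows.append(dict(patient_id=pw.patient_id, metric=m,
                             p24=cyc.p24, significant=cyc.significant,
                             alpha_hat=cyc.alpha_hat, plv=pv, n_seizures=n_sz))
    return pd.DataFrame(rows), hourly_store
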