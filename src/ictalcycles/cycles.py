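"""24-h cycle detection in hourly series against a red-noise null.

Hourly metric series are cleaned (missing hours interpolated, >3 sigma
outliers replaced), turned into Welch periodograms, and the power at the
24-h bin is tested against a Monte-Carlo null built from a fitted red-noise
spectrum 1/f^alpha: the log-log linear fit (24-h and 12-h bins excluded)
gives the null mean at each frequency and the residual variance gives the
null spread; simulated 24-h-bin values are drawn as Gaussian deviates in
the log-power domain and compared with the observed value.

The Welch segment length is 96 hours (4 days, 50% overlap, Hann window) so
that 1/24 cycles/hour falls exactly on a frequency bin; shorter series fall
back to a single full-length segment and the nearest bin is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

WELCH_SEGMENT_H = 96
DEFAULT_N_SIM = 10_000
EXCLUDE_PERIODS_H = (24.0, 12.0)


@dataclass
class CycleResult:
    frequencies: np.ndarray      # cycles/hour
    power: np.ndarray
    alpha_hat: float             # red-noise exponent
    noise_scale: float           # log10 power at f = 1 cycle/hour
    resid_var: float             # residual variance about the log-log fit
    p24: float
    significant: bool
    period_h: float = 24.0
    degenerate: bool = False


def clean_series(values: np.ndarray, missing: np.ndarray | None = None,
                 z_thresh: float = 3.0, max_missing_frac: float = 0.5,
                 min_hours: int = 48) -> np.ndarray:
    """Interpolate missing hours and replace >3 sigma outliers.

    Interior gaps are linearly interpolated; leading/trailing gaps take the
    nearest valid value.  Outliers are detected on the gap-filled series
    and replaced by interpolation from their non-outlier neighbours.
    """
    v = np.asarray(values, dtype=float).copy()
    if missing is None:
        missing = np.isnan(v)
    else:
        missing = np.asarray(missing, dtype=bool) | np.isnan(v)
    n = len(v)
    if n < min_hours:
        raise ValueError(f"need at least {min_hours} hourly points, got {n}")
    if missing.mean() > max_missing_frac:
        raise ValueError("more than half of the hours are missing")
    idx = np.arange(n)
    v[missing] = np.interp(idx[missing], idx[~missing], v[~missing])
    sd = v.std()
    if sd > 0:
        z = (v - v.mean()) / sd
        out = np.abs(z) > z_thresh
        if out.any() and not out.all():
            v[out] = np.interp(idx[out], idx[~out], v[~out])
    return v


def periodogram(series: np.ndarray, segment_h: int = WELCH_SEGMENT_H):
    """Welch periodogram of an hourly series (frequencies in cycles/hour)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    nper = min(segment_h, n)
    if nper < 8:
        raise ValueError("series shorter than one usable Welch segment")
    f, p = sps.welch(x - x.mean(), fs=1.0, window="hann", nperseg=nper,
                     noverlap=nper // 2, detrend="constant")
    return f, p


def _bin_at_period(frequencies: np.ndarray, period_h: float) -> int:
    return int(np.argmin(np.abs(frequencies - 1.0 / period_h)))


def fit_red_noise(frequencies: np.ndarray, power: np.ndarray,
                  exclude_periods_h: tuple[float, ...] = EXCLUDE_PERIODS_H):
    """Least-squares 1/f^alpha fit to the log-log periodogram.

    The bins nearest the excluded periods (24 h and 12 h by default) and
    any non-positive bins are left out.  Returns ``(alpha_hat,
    noise_scale, resid_var)`` where the fitted null mean in log10 power is
    ``noise_scale - alpha_hat * log10(f)``.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    keep = (f > 0) & (p > 0)
    for per in exclude_periods_h:
        b = _bin_at_period(f, per)
        keep[b] = False
    if keep.sum() < 8:
        raise ValueError("fewer than 8 usable periodogram bins for the fit")
    lf, lp = np.log10(f[keep]), np.log10(p[keep])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (intercept + slope * lf)
    return -slope, intercept, float(resid.var())


def mc_pvalue(frequencies: np.ndarray, power: np.ndarray,
              alpha_hat: float, noise_scale: float, resid_var: float,
              period_h: float = 24.0, n_sim: int = DEFAULT_N_SIM,
              rng: np.random.Generator | int | None = None,
              global_peak: bool = False) -> float:
    """Monte-Carlo p-value for the peak at ``period_h``.

    Simulated periodogram values are drawn in the log-power domain as the
    fitted red-noise mean plus Gaussian noise with the fitted residual
    variance; the add-one estimator (1 + #exceed) / (n_sim + 1) avoids
    p = 0.  With ``global_peak`` the simulated spectra are compared by
    their maximum excess over the null mean across all bins (a more
    conservative reading of "a peak larger than the peak measured").
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable p-values")
    rng = np.random.default_rng(rng)
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    b = _bin_at_period(f, period_h)
    sd = np.sqrt(max(resid_var, 0.0))
    null_mean_b = noise_scale - alpha_hat * np.log10(f[b])
    obs = np.log10(max(p[b], 1e-300))
    if global_peak:
        pos = f > 0
        null_mean = noise_scale - alpha_hat * np.log10(f[pos])
        sims = null_mean + sd * rng.standard_normal((n_sim, pos.sum()))
        sim_stat = (sims - null_mean).max(axis=1)
        obs_stat = obs - null_mean_b
    else:
        sim_stat = null_mean_b + sd * rng.standard_normal(n_sim)
        obs_stat = obs
    exceed = int(np.sum(sim_stat >= obs_stat))
    return (1 + exceed) / (n_sim + 1)


def detect_cycle(hourly_values: np.ndarray, missing: np.ndarray | None = None,
                 period_h: float = 24.0, n_sim: int = DEFAULT_N_SIM,
                 rng: np.random.Generator | int | None = None,
                 alpha_level: float = 0.05, segment_h: int = WELCH_SEGMENT_H,
                 global_peak: bool = False) -> CycleResult:
    """Full cycle test for one hourly series.

    Degenerate series (zero variance after cleaning, e.g. a metric that is
    identically zero on the sampled channels) are reported as
    non-significant with p = 1.
    """
    cleaned = clean_series(hourly_values, missing)
    if cleaned.std() == 0:
        return CycleResult(frequencies=np.empty(0), power=np.empty(0),
                           alpha_hat=np.nan, noise_scale=np.nan, resid_var=np.nan,
                           p24=1.0, significant=False, period_h=period_h,
                           degenerate=True)
    f, p = periodogram(cleaned, segment_h=segment_h)
    alpha_hat, scale, resid_var = fit_red_noise(f, p)
    p24 = mc_pvalue(f, p, alpha_hat, scale, resid_var, period_h=period_h,
                    n_sim=n_sim, rng=rng, global_peak=global_peak)
    return CycleResult(frequencies=f, power=p, alpha_hat=alpha_hat,
                       noise_scale=scale, resid_var=resid_var, p24=p24,
                       significant=bool(p24 < alpha_level), period_h=period_h)
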