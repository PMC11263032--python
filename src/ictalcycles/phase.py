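"""Cycle phase extraction and seizure phase locking.

The hourly metric series is band-passed to periods of 2-30 hours with a
zero-phase first-order Butterworth filter (applied forward-backward), the
instantaneous phase is taken from the analytic signal, each seizure is
assigned the phase of its onset hour, and the phase-locking value (PLV) is
the modulus of the mean unit phasor over seizures: 1 when every seizure
occurs at the same cycle phase, ~1/sqrt(S) for S seizures at random phases.

A data-free reference cycle, the cosine daily function (CDF), is a pure
24-h cosine of wall-clock time; running it through the same machinery
quantifies how much of a metric's phase locking is explained by the clock
alone.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .metrics import HourlySeries

PERIOD_BAND_H = (2.0, 30.0)


def cycle_phase(hourly_values: np.ndarray,
                period_band_h: tuple[float, float] = PERIOD_BAND_H,
                pad_h: int = 72) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) of the 2-30 h cycle.

    The upper band edge (2 h period = the Nyquist frequency of an hourly
    series) is pulled fractionally inside Nyquist for a realizable filter.
    Phase 0 falls at cycle peaks.  The series is mirror-extended by
    ``pad_h`` hours before filtering and the FFT Hilbert transform, then
    cropped: without padding the analytic-signal phase is badly distorted
    over roughly the first and last day, which would depress the PLV of
    seizures occurring there.
    """
    x = np.asarray(hourly_values, dtype=float)
    n = len(x)
    if n < 60:
        raise ValueError("need at least 60 hourly points for phase estimation")
    p = min(pad_h, n - 1)
    xe = np.pad(x - x.mean(), p, mode="reflect")
    lo = 1.0 / period_band_h[1]
    hi = min(1.0 / period_band_h[0], 0.499)
    sos = sps.butter(1, [lo, hi], btype="bandpass", fs=1.0, output="sos")
    filt = sps.sosfiltfilt(sos, xe)
    return np.angle(sps.hilbert(filt))[p: p + n]


def seizure_phases(phase_series: np.ndarray, seizure_onsets_s: np.ndarray,
                   hour_offset_s: float = 0.0):
    """Phase of the onset hour for every seizure.

    Seizures outside the series span are dropped.  Returns ``(phases,
    n_dropped)``.
    """
    phases = []
    dropped = 0
    n = len(phase_series)
    for t in np.atleast_1d(np.asarray(seizure_onsets_s, dtype=float)):
        h = int((t - hour_offset_s) // 3600.0)
        if 0 <= h < n:
            phases.append(phase_series[h])
        else:
            dropped += 1
    return np.asarray(phases), dropped


def plv(phases: np.ndarray, literal_re: bool = False) -> float:
    """Phase-locking value: modulus of the mean unit phasor.

    ``literal_re`` evaluates the real part of the mean phasor instead
    (the printed equation form; not confined to [0, 1]).
    """
    ph = np.atleast_1d(np.asarray(phases, dtype=float))
    if ph.size == 0:
        return float("nan")
    z = np.exp(1j * ph).mean()
    return float(np.real(z) if literal_re else np.abs(z))


def cdf_reference(hour_of_day: np.ndarray, phi0: float = 0.0,
                  metric: str = "CDF") -> HourlySeries:
    """Cosine daily function: cos(2 pi h / 24 - phi0) of wall-clock hour.

    The default phase origin puts the peak at midnight; phi0 shifts it.
    """
    h = np.asarray(hour_of_day, dtype=float)
    v = np.cos(2 * np.pi * h / 24.0 - phi0)
    return HourlySeries(values=v, missing=np.zeros(len(v), dtype=bool),
                        hour_of_day=h.astype(int), metric=metric)
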