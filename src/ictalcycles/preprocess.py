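"""Filtering, downsampling and band-power preprocessing.

The chain applied to every recording before metric computation:

1. 50 Hz notch (power-line), zero-phase second-order IIR, Q = 30.
2. Zero-phase 4th-order Butterworth high-pass at 0.1 Hz (drift removal)
   and low-pass at 95 Hz (also removes the 100 Hz line harmonic).
3. Fourier-method downsampling to 256 Hz.
4. Optional band-pass into the canonical bands (theta/alpha/beta/gamma/
   broadband; delta available but off by default).
5. Band-power fluctuation series: log10 power in non-overlapping 125 ms
   frames (single Hann-windowed Welch segment per frame), 8 frames/s.
6. Per-hour z-scoring of each channel.

All filters are applied forward-backward (two-pass) so they are zero
phase-lag; the nominal Butterworth order refers to the one-pass design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

#: Canonical analysis bands (Hz).  Delta is exposed for completeness but is
#: not part of the default outputs (broadband behaves near-identically).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (55.0, 95.0),
    "broadband": (1.0, 99.0),
    "delta": (1.0, 4.0),
}

DEFAULT_BANDS = ("theta", "alpha", "beta", "gamma", "broadband")

FRAME_STEP_S = 0.125  #: power-fluctuation frame step (8 frames per second)
POWER_FLOOR = 1e-12  #: linear-power floor before log10 (silent frames)


@dataclass
class BandSpec:
    name: str
    lo: float
    hi: float


def get_band(name: str) -> BandSpec:
    try:
        lo, hi = BANDS[name]
    except KeyError:
        raise ValueError(f"unknown band {name!r}; choose from {sorted(BANDS)}") from None
    return BandSpec(name, lo, hi)


@dataclass
class PowerSeries:
    """Log10 band power in non-overlapping 125 ms frames, per channel."""

    values: np.ndarray  # (n_channels, n_frames)
    frame_step: float
    band: BandSpec

    @property
    def frames_per_second(self) -> float:
        return 1.0 / self.frame_step


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def base_filter(rec: Recording, notch_hz: float = 50.0, notch_q: float = 30.0,
                hp_hz: float = 0.1, lp_hz: float = 95.0) -> Recording:
    """Notch + high-pass + low-pass chain (zero phase-lag)."""
    if rec.fs <= 2 * lp_hz:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {lp_hz} Hz low-pass"
        )
    b, a = sps.iirnotch(notch_hz, notch_q, fs=rec.fs)
    x = sps.filtfilt(b, a, rec.signal, axis=-1)
    sos_hp = sps.butter(4, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x, axis=-1)
    sos_lp = sps.butter(4, lp_hz, btype="lowpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos_lp, x, axis=-1)
    return rec.with_signal(x)


def downsample_to(rec: Recording, target_fs: float = 256.0) -> Recording:
    """Fourier-method downsampling; never upsamples."""
    if rec.fs < target_fs:
        raise ValueError(f"cannot upsample from {rec.fs} to {target_fs} Hz")
    if rec.fs == target_fs:
        return rec
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    x = sps.resample(rec.signal, n_out, axis=-1)
    return rec.with_signal(x, fs=target_fs)


def band_filter(rec: Recording, band: str | BandSpec) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass into a canonical band."""
    spec = get_band(band) if isinstance(band, str) else band
    sos = sps.butter(4, [spec.lo, spec.hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_signal(sps.sosfiltfilt(sos, rec.signal, axis=-1))


def preprocess(rec: Recording, target_fs: float = 256.0) -> Recording:
    """Full base chain: base_filter then downsample."""
    return downsample_to(base_filter(rec), target_fs)


# ---------------------------------------------------------------------------
# band-power fluctuation series
# ---------------------------------------------------------------------------

def frame_power(x: np.ndarray, fs: float, frame_step: float = FRAME_STEP_S) -> np.ndarray:
    """Mean power per non-overlapping frame (single Hann Welch segment).

    ``x`` has shape (..., n_samples); trailing samples that do not fill a
    whole frame are dropped.  The returned linear power equals the
    Hann-weighted mean square of the frame, i.e. the integral of the
    one-sided Welch PSD over frequency.
    """
    frame_len = fs * frame_step
    if abs(frame_len - round(frame_len)) > 1e-9:
        raise ValueError(f"fs={fs} does not give an integer {frame_step}s frame")
    frame_len = int(round(frame_len))
    n_frames = x.shape[-1] // frame_len
    if n_frames < 1:
        raise ValueError("segment shorter than one frame")
    xw = x[..., : n_frames * frame_len].reshape(*x.shape[:-1], n_frames, frame_len)
    w = sps.get_window("hann", frame_len)
    return np.sum((xw * w) ** 2, axis=-1) / np.sum(w**2)


def power_fluctuations(rec: Recording, band: str | BandSpec = "gamma") -> PowerSeries:
    """Log10 band-power series at 8 frames/s for every channel."""
    spec = get_band(band) if isinstance(band, str) else band
    filtered = band_filter(rec, spec)
    p = frame_power(filtered.signal, rec.fs)
    return PowerSeries(values=np.log10(np.maximum(p, POWER_FLOOR)),
                       frame_step=FRAME_STEP_S, band=spec)


# ---------------------------------------------------------------------------
# hourly normalization
# ---------------------------------------------------------------------------

def normalize_hour(x: np.ndarray):
    """Z-score each channel over an hour-long segment.

    Returns ``(z, degenerate)`` where ``degenerate`` flags zero-variance
    channels (left all-zero).
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    degenerate = (sd[..., 0] == 0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    if np.any(degenerate):
        z = np.where(degenerate[..., None], 0.0, z)
    return z, degenerate
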