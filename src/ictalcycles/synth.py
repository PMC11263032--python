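"""Synthetic multi-patient iEEG cohorts with known planted structure.

Every pipeline stage is validated against cohorts generated here: 1/f^alpha
colored background activity, circadian (24-h) modulation of variance, power
autocorrelation time, inter-channel coupling and discharge rate, spike-wave
discharge events on seizure-onset-zone channels, and seizure times drawn at
a concentrated phase (von Mises) of the circadian driver.

Two generation levels are provided:

* :func:`simulate_recording` synthesizes a full continuous multichannel
  signal (a :class:`~ictalcycles.recording.Recording`) and is used at small
  scale, where every preprocessing and metric stage can run end-to-end.
* :func:`simulate_patient_windows` / :func:`simulate_cohort` synthesize the
  quantity each metric actually consumes per 2-min window (broadband
  window variance, AR(1) log-power frames, Poisson discharge counts, phase
  ensembles, shared-driver frames), which makes multi-day multi-patient
  cohorts tractable: days of continuous raw signal at 256 Hz would run to
  tens of gigabytes per patient.  Window variances are drawn through the
  exact Parseval identity on the synthesized spectrum, so their
  distribution is identical to computing the sample variance of the
  explicit time-domain window (a unit test asserts the identity).

The circadian driver common to all modulated processes is
``cos(2 pi t / period - circadian_phase - J_d)`` where ``J_d`` is a slow
day-to-day random-walk drift of the physiological phase against the wall
clock.  Without this drift a pure clock cosine would phase-lock to
seizures exactly as well as the metrics themselves (the phase-locking
value is rotation invariant), so the drift is what lets the data-free
clock reference underperform metrics that track the actual driver.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .metrics import WindowGrid, build_window_grid, scm_metric, kuramoto_order, tcm_metric
from .recording import Recording

SECONDS_PER_DAY = 86400.0


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the real cohort where it is described (channel counts
    40-120, sampling 256/512/1024 Hz, 5-14 days, 23 patients) and plant
    mid-range modulation elsewhere.
    """

    n_patients: int = 23
    n_channels: int = 60
    fs: float = 256.0
    n_days: int = 10
    spectral_exponent: float = 1.5      # 1/f^alpha background
    circadian_depth: float = 0.5        # fractional amplitude modulation
    circadian_period_h: float = 24.0
    circadian_phase: float = 0.0        # driver peak (radians past midnight)
    circadian_phase_jitter: float = 0.35  # rad/day random-walk drift vs clock
    ied_rate_base: float = 0.5          # events/channel/min on SOZ channels
    ied_rate_depth: float = 0.5
    ied_non_soz_frac: float = 0.0       # off-SOZ false-detection floor (unmodulated)
    ied_amplitude: float = 8.0          # template peak, x background std
    n_seizures: int = 20
    seizure_phase_mu: float = 0.0
    seizure_phase_kappa: float = 2.0
    seizure_duration_s: float = 60.0
    coupling_depth: float = 0.3         # modulation of shared-signal mixing
    # coupling_base keeps the shared gamma line a realistic few percent of
    # total variance in raw-signal recordings
    coupling_base: float = 0.15
    electrode_spacing: float = 10.0     # mm, regular 3-D grid
    n_soz_channels: int = 3
    windows_per_hour: int = 30          # duty cycle of window-level cohorts
    tcm_tau_base: float = 0.2           # s, baseline power-ACF half-decay
    ns_base: float = 0.5                # baseline Kuramoto order parameter
    scm_base: float = 0.4               # baseline 10-80 mm pair correlation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("circadian_depth", "ied_rate_depth", "coupling_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fs not in (256.0, 512.0, 1024.0, 256, 512, 1024):
            raise ValueError("fs must be 256, 512 or 1024 Hz")
        if min(self.n_patients, self.n_channels, self.n_days, self.n_seizures) < 1:
            raise ValueError("counts must be positive")
        if self.seizure_phase_kappa < 0:
            raise ValueError("von Mises kappa must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic patient."""

    seizure_phases: np.ndarray           # radians, relative to the driver
    seizure_onsets_s: np.ndarray
    circadian_phase: float
    circadian_period_h: float
    day_jitter: np.ndarray               # J_d per day, radians
    circadian_depth: float
    ied_times: dict = field(default_factory=dict)  # channel -> event times (s)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def colored_spectrum_amplitudes(n_samples: int, fs: float, alpha: float,
                                f_min: float = 0.5) -> np.ndarray:
    """rfft amplitude profile of unit-variance 1/f^alpha noise.

    Amplitudes follow f^(-alpha/2) above ``f_min`` and are flat below it
    (keeps the lowest bins finite); the DC bin is zero, so realizations are
    exactly zero-mean.  Scaled so the expected *sample* variance (ddof=1)
    of the time-domain realization is 1.
    """
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.ones_like(f)
    if alpha > 0:
        fc = np.maximum(f, f_min)
        amp = fc ** (-alpha / 2.0)
    amp[0] = 0.0
    # E[sum x^2] = (2 * sum_{1..K-1} 2 amp^2 + amp_K^2) / n  (rfft convention)
    e_ss = (4.0 * np.sum(amp[1:-1] ** 2) + amp[-1] ** 2 * (2.0 if n_samples % 2 else 1.0)) / n_samples
    if n_samples % 2:  # odd length: no pure-real Nyquist bin
        e_ss = 4.0 * np.sum(amp[1:] ** 2) / n_samples
    return amp * np.sqrt((n_samples - 1) / e_ss)


def generate_background(n_channels: int, fs: float, duration_s: float,
                        spectral_exponent: float,
                        rng: np.random.Generator | int | None = None,
                        variance: float = 1.0) -> np.ndarray:
    """Independent zero-mean 1/f^alpha channels, expected variance ``variance``."""
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * fs))
    amp = colored_spectrum_amplitudes(n, fs, spectral_exponent) * np.sqrt(variance)
    k = len(amp)
    spec = amp * (rng.standard_normal((n_channels, k)) + 1j * rng.standard_normal((n_channels, k)))
    spec[:, 0] = 0.0
    if n % 2 == 0:  # Nyquist bin must be real; variance 2 amp^2 like interior bins
        spec[:, -1] = amp[-1] * np.sqrt(2.0) * rng.standard_normal(n_channels)
    return np.fft.irfft(spec, n, axis=-1)


def apply_circadian_modulation(signal: np.ndarray, fs: float, depth: float,
                               period_h: float = 24.0, phase: float = 0.0,
                               t0_s: float = 0.0) -> np.ndarray:
    """Multiply the amplitude envelope by 1 + depth cos(2 pi t/T - phase)."""
    if not 0.0 <= depth <= 1.0:
        raise ValueError(f"depth must be in [0, 1], got {depth}")
    if depth == 0.0:
        return np.asarray(signal, dtype=float)
    x = np.asarray(signal, dtype=float)
    t = t0_s + np.arange(x.shape[-1]) / fs
    env = 1.0 + depth * np.cos(2 * np.pi * t / (period_h * 3600.0) - phase)
    return x * env


def ied_template(fs: float, amplitude: float = 1.0, spike_sigma_ms: float = 4.0,
                 wave_ms: float = 200.0) -> np.ndarray:
    """Spike-wave transient: sharp Gaussian spike then a slow opposite wave."""
    n_spike = int(round(0.06 * fs))
    t = (np.arange(2 * n_spike + 1) - n_spike) / fs
    spike = np.exp(-(t / (spike_sigma_ms / 1000.0)) ** 2)
    n_wave = int(round(wave_ms / 1000.0 * fs))
    wave = -0.4 * np.sin(np.pi * np.arange(n_wave) / n_wave)
    return amplitude * np.concatenate([spike, wave])


def inject_ieds(signal: np.ndarray, fs: float, channel_idx,
                rate_per_min, template: np.ndarray,
                rng: np.random.Generator | int | None = None):
    """Add spike-wave events from an inhomogeneous Poisson process.

    ``rate_per_min`` is either a scalar or an array of per-minute rates
    (one entry per whole minute of the signal).  Returns ``(signal,
    events)`` with ``events`` mapping channel index to event times in
    seconds (the template peak position).
    """
    rng = np.random.default_rng(rng)
    x = np.array(signal, dtype=float)
    n = x.shape[-1]
    if len(template) > n:
        raise ValueError("template longer than the signal")
    n_min = int(n / fs // 60)
    rates = np.broadcast_to(np.atleast_1d(np.asarray(rate_per_min, dtype=float)),
                            (max(n_min, 1),))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    peak = int(np.argmax(np.abs(template)))
    events: dict[int, np.ndarray] = {}
    for c in np.atleast_1d(channel_idx):
        times = []
        for m in range(max(n_min, 1)):
            k = rng.poisson(rates[m])
            times.extend(60.0 * m + 60.0 * rng.random(k))
        times = np.sort(times)
        kept = []
        for t in times:
            start = int(round(t * fs)) - peak
            if start < 0 or start + len(template) > n:
                continue
            x[c, start: start + len(template)] += template
            kept.append(start / fs + peak / fs)
        events[int(c)] = np.asarray(kept)
    return x, events


def sample_seizure_times(n_seizures: int, mu: float, kappa: float,
                         period_h: float, n_days: int,
                         rng: np.random.Generator | int | None = None,
                         phase_offset: float = 0.0,
                         day_jitter: np.ndarray | None = None,
                         duration_s: float = 60.0):
    """Seizure intervals whose driver phases are von Mises(mu, kappa).

    Each seizure gets a uniformly random day; its clock time on that day is
    the time at which the (possibly drifting) driver reaches the sampled
    phase.  Returns ``(intervals, true_phases)`` with intervals (onset,
    offset) in seconds from the start of day 0.
    """
    if n_seizures < 1:
        raise ValueError("need at least one seizure")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(rng)
    if kappa > 1e5:  # numerically degenerate von Mises: all mass at mu
        theta = mu + rng.standard_normal(n_seizures) / np.sqrt(kappa)
    elif kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, n_seizures)
    else:
        theta = rng.vonmises(mu, kappa, n_seizures)
    days = rng.integers(0, n_days, n_seizures)
    jit = np.zeros(n_days) if day_jitter is None else np.asarray(day_jitter)
    frac = np.mod(theta + phase_offset + jit[days], 2 * np.pi) / (2 * np.pi)
    onsets = days * SECONDS_PER_DAY + frac * period_h * 3600.0
    order = np.argsort(onsets)
    intervals = np.column_stack([onsets, onsets + duration_s])[order]
    theta = np.mod(theta[order] + np.pi, 2 * np.pi) - np.pi
    return intervals, theta


def day_jitter_walk(n_days: int, step_rad: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Random-walk drift of the circadian driver phase, one value per day."""
    if step_rad == 0:
        return np.zeros(n_days)
    steps = step_rad * rng.standard_normal(n_days)
    steps[0] = 0.0
    return np.cumsum(steps)


def generate_hourly_red_noise(n_hours: int, alpha: float,
                              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Pure 1/f^alpha hourly series (unit expected variance, no planted cycle)."""
    rng = np.random.default_rng(rng)
    f = np.fft.rfftfreq(n_hours, d=1.0)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-alpha / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f)))
    x = np.fft.irfft(spec, n_hours)
    return x / x.std()


def electrode_grid(n_channels: int, spacing_mm: float) -> np.ndarray:
    """Regular 3-D grid of electrode coordinates (mm).

    The real geometry is unknown (only the 10-80 mm analysis band is); a
    grid at 10 mm spacing populates that band densely.
    """
    side = int(np.ceil(n_channels ** (1.0 / 3.0)))
    pts = np.array([(i, j, k) for i in range(side) for j in range(side)
                    for k in range(side)][:n_channels], dtype=float)
    return pts * spacing_mm


# ---------------------------------------------------------------------------
# full-signal recording (small scale)
# ---------------------------------------------------------------------------

def simulate_recording(cfg: SyntheticConfig, duration_s: float | None = None,
                       rng: np.random.Generator | int | None = None):
    """Continuous multichannel recording with planted structure.

    Intended for short durations (unit and end-to-end tests); the cohort
    generators below cover multi-day scales.  Returns ``(Recording,
    GroundTruth)``.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    dur = float(duration_s if duration_s is not None else cfg.n_days * SECONDS_PER_DAY)
    n_days = max(1, int(np.ceil(dur / SECONDS_PER_DAY)))
    jitter = day_jitter_walk(n_days, cfg.circadian_phase_jitter, rng)

    x = generate_background(cfg.n_channels, cfg.fs, dur, cfg.spectral_exponent, rng)
    n = x.shape[-1]
    t = np.arange(n) / cfg.fs
    day_of = np.minimum((t // SECONDS_PER_DAY).astype(int), n_days - 1)
    phi = (2 * np.pi * t / (cfg.circadian_period_h * 3600.0)
           - cfg.circadian_phase - jitter[day_of])

    if cfg.coupling_base > 0:
        shared = generate_background(1, cfg.fs, dur, 0.0, rng)[0]
        sos = sps.butter(4, [55.0, 95.0], btype="bandpass", fs=cfg.fs, output="sos")
        shared = sps.sosfiltfilt(sos, shared)
        shared /= shared.std()
        w = np.clip(cfg.coupling_base * (1.0 + cfg.coupling_depth * np.cos(phi)), 0.0, 0.99)
        x = np.sqrt(1.0 - w**2) * x + w * shared

    x *= 1.0 + cfg.circadian_depth * np.cos(phi)

    soz_idx = np.arange(min(cfg.n_soz_channels, cfg.n_channels))
    n_min = max(1, int(dur // 60))
    t_min = 60.0 * np.arange(n_min) + 30.0
    d_min = np.minimum((t_min // SECONDS_PER_DAY).astype(int), n_days - 1)
    phi_min = (2 * np.pi * t_min / (cfg.circadian_period_h * 3600.0)
               - cfg.circadian_phase - jitter[d_min])
    rate = cfg.ied_rate_base * (1.0 + cfg.ied_rate_depth * np.cos(phi_min))
    template = ied_template(cfg.fs, amplitude=cfg.ied_amplitude * x.std())
    x, ied_times = inject_ieds(x, cfg.fs, soz_idx, rate, template, rng)

    intervals, phases = sample_seizure_times(
        cfg.n_seizures, cfg.seizure_phase_mu, cfg.seizure_phase_kappa,
        cfg.circadian_period_h, n_days, rng,
        phase_offset=cfg.circadian_phase, day_jitter=jitter,
        duration_s=cfg.seizure_duration_s)
    inside = intervals[:, 1] <= dur
    intervals, phases = intervals[inside], phases[inside]

    labels = [f"CH{i + 1:03d}" for i in range(cfg.n_channels)]
    rec = Recording(signal=x, fs=cfg.fs, channel_labels=labels,
                    electrode_xyz=electrode_grid(cfg.n_channels, cfg.electrode_spacing),
                    start_time=_dt.datetime(2024, 1, 1, 0, 0, 0),
                    seizures=intervals,
                    soz_channels=[labels[i] for i in soz_idx])
    truth = GroundTruth(seizure_phases=phases, seizure_onsets_s=intervals[:, 0],
                        circadian_phase=cfg.circadian_phase,
                        circadian_period_h=cfg.circadian_period_h,
                        day_jitter=jitter, circadian_depth=cfg.circadian_depth,
                        ied_times=ied_times)
    return rec, truth


# ---------------------------------------------------------------------------
# window-level cohort (multi-day scale)
# ---------------------------------------------------------------------------

def variance_draws(n_draws: int, amp: np.ndarray, n_samples: int,
                   rng: np.random.Generator, chunk: int = 1000) -> np.ndarray:
    """Sample variances of colored-noise windows via the Parseval identity.

    For a window synthesized as ``x = irfft(amp * (a + i b))`` with unit
    normal a, b the sample variance is a deterministic function of the
    spectrum magnitudes (the mean is exactly zero since amp[0] = 0):
    ``var = sum |X_k|^2_two-sided / (n (n-1))`` with ``|X_k|^2 = 2 amp_k^2
    e_k`` and ``e_k ~ Exp(1)``.  Drawing the exponentials directly is
    distribution-identical to generating the window and computing its
    variance, at a fraction of the cost.
    """
    a2 = amp[1:-1] ** 2 if n_samples % 2 == 0 else amp[1:] ** 2
    scale = 1.0 / (n_samples * (n_samples - 1))
    out = np.empty(n_draws)
    for s in range(0, n_draws, chunk):
        m = min(chunk, n_draws - s)
        e = rng.exponential(size=(m, len(a2)))
        tot = 4.0 * (e @ a2)
        if n_samples % 2 == 0:
            tot += amp[-1] ** 2 * 2.0 * rng.standard_normal(m) ** 2
        out[s: s + m] = scale * tot
    return out


def ar1_frames(phi: np.ndarray, n_frames: int,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series (one per row) with per-row coefficient."""
    phi = np.asarray(phi, dtype=float)
    b = len(phi)
    x = np.empty((b, n_frames))
    x[:, 0] = rng.standard_normal(b) / np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((b, n_frames - 1))
    for t in range(1, n_frames):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


@dataclass
class PatientWindows:
    """Window-level metric values for one (synthetic) patient."""

    patient_id: int
    grid: WindowGrid
    hour_of_day: np.ndarray
    values: dict                      # metric -> (n_windows,) or (n_windows, n_ch)
    soz_mask: np.ndarray
    electrode_xyz: np.ndarray
    seizure_onsets_s: np.ndarray
    truth: GroundTruth


def simulate_patient_windows(cfg: SyntheticConfig, patient_id: int = 0,
                             rng: np.random.Generator | int | None = None,
                             metrics: tuple[str, ...] = ("VM", "TCM", "IEDF"),
                             frames_per_window: int = 960,
                             ns_samples: int = 160) -> PatientWindows:
    """One synthetic patient at the window level.

    Each requested metric's per-window values are drawn from the process
    the metric consumes, all modulated by the common circadian driver
    (depths from the config).  ``windows_per_hour`` < 30 duty-cycles the
    hour (windows taken from the start of each hour), which scales cohort
    generation down without touching the planted structure.
    """
    rng = np.random.default_rng(cfg.seed + 7919 * patient_id if rng is None else rng)
    n_hours = cfg.n_days * 24
    hb = np.column_stack([3600.0 * np.arange(n_hours), 3600.0 * np.arange(1, n_hours + 1)])
    jitter = day_jitter_walk(cfg.n_days, cfg.circadian_phase_jitter, rng)
    intervals, sz_phases = sample_seizure_times(
        cfg.n_seizures, cfg.seizure_phase_mu, cfg.seizure_phase_kappa,
        cfg.circadian_period_h, cfg.n_days, rng,
        phase_offset=cfg.circadian_phase, day_jitter=jitter,
        duration_s=cfg.seizure_duration_s)
    grid = build_window_grid(hb, intervals, windows_per_hour=cfg.windows_per_hour)

    t_c = grid.windows.mean(axis=1)
    day_of = np.minimum((t_c // SECONDS_PER_DAY).astype(int), cfg.n_days - 1)
    phi_w = (2 * np.pi * t_c / (cfg.circadian_period_h * 3600.0)
             - cfg.circadian_phase - jitter[day_of])
    mod = np.cos(phi_w)
    n_w = len(t_c)
    nch = cfg.n_channels
    soz = np.zeros(nch, dtype=bool)
    soz[: min(cfg.n_soz_channels, nch)] = True
    values: dict[str, np.ndarray] = {}

    if "VM" in metrics:
        n_samp = int(round(cfg.fs * grid.window_len))
        amp = colored_spectrum_amplitudes(n_samp, cfg.fs, cfg.spectral_exponent)
        env2 = (1.0 + cfg.circadian_depth * mod) ** 2
        draws = variance_draws(n_w * nch, amp, n_samp, rng).reshape(n_w, nch)
        values["VM"] = draws * env2[:, None]

    if "TCM" in metrics:
        tau = cfg.tcm_tau_base * (1.0 + cfg.circadian_depth * mod)
        phi_ar = np.clip(0.5 ** (0.125 / np.maximum(tau, 1e-3)), 0.01, 0.98)
        vals = np.empty((n_w, nch))
        chunk = max(1, 20000 // max(nch, 1))
        for s in range(0, n_w, chunk):
            m = min(chunk, n_w - s)
            co = np.repeat(phi_ar[s: s + m], nch)
            frames = ar1_frames(co, frames_per_window, rng)
            vals[s: s + m] = tcm_metric(frames).reshape(m, nch)
        values["TCM"] = vals

    if "IEDF" in metrics:
        # discharges are a property of epileptogenic (SOZ) tissue: only SOZ
        # channels carry the circadian-modulated rate; off-SOZ events are a
        # small unmodulated false-detection floor (0 by default)
        rate = cfg.ied_rate_base * (1.0 + cfg.ied_rate_depth * mod)
        lam = np.where(soz[None, :], rate[:, None],
                       cfg.ied_rate_base * cfg.ied_non_soz_frac)
        counts = rng.poisson(lam * (grid.window_len / 60.0))
        values["IEDF"] = counts / (grid.window_len / 60.0)  # events/channel/min

    if "NS" in metrics:
        s_w = np.clip(cfg.ns_base * (1.0 + cfg.coupling_depth * mod), 0.01, 0.99)
        sigma = np.sqrt(-2.0 * np.log(s_w))
        ns = np.empty(n_w)
        for i in range(n_w):
            theta = sigma[i] * rng.standard_normal((nch, ns_samples))
            ns[i] = kuramoto_order(theta).mean()
        values["NS"] = ns

    if "SCM" in metrics:
        xyz = electrode_grid(nch, cfg.electrode_spacing)
        rho = np.clip(cfg.scm_base * (1.0 + cfg.coupling_depth * mod), 0.0, 0.97)
        scm = np.empty(n_w)
        for i in range(n_w):
            g = rng.standard_normal(frames_per_window)
            eps = rng.standard_normal((nch, frames_per_window))
            frames = np.sqrt(rho[i]) * g + np.sqrt(1.0 - rho[i]) * eps
            scm[i] = scm_metric(frames, xyz)
        values["SCM"] = scm

    truth = GroundTruth(seizure_phases=sz_phases, seizure_onsets_s=intervals[:, 0],
                        circadian_phase=cfg.circadian_phase,
                        circadian_period_h=cfg.circadian_period_h,
                        day_jitter=jitter, circadian_depth=cfg.circadian_depth)
    return PatientWindows(patient_id=patient_id, grid=grid,
                          hour_of_day=np.arange(n_hours) % 24,
                          values=values, soz_mask=soz,
                          electrode_xyz=electrode_grid(nch, cfg.electrode_spacing),
                          seizure_onsets_s=intervals[:, 0], truth=truth)


def simulate_cohort(cfg: SyntheticConfig,
                    metrics: tuple[str, ...] = ("VM", "TCM", "IEDF"),
                    rng: np.random.Generator | int | None = None,
                    **kwargs) -> list[PatientWindows]:
    """Window-level cohort of ``cfg.n_patients`` independent patients."""
    master = np.random.default_rng(cfg.seed if rng is None else rng)
    seeds = master.integers(0, 2**31 - 1, cfg.n_patients)
    return [simulate_patient_windows(cfg, patient_id=i,
                                     rng=np.random.default_rng(int(s)),
                                     metrics=metrics, **kwargs)
            for i, s in enumerate(seeds)]
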