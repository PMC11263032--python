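"""Recording container and I/O (internal HDF5 layout and 16-bit EDF).

A :class:`Recording` bundles one patient's continuous multichannel iEEG
signal with the metadata the pipeline needs: sampling rate, channel labels,
3-D electrode coordinates, seizure onset/offset intervals, and the clinician
labelled seizure-onset-zone (SOZ) channels.  Recordings are assumed to be
organised as contiguous hour-long segments; segments shorter than one hour
are dropped before analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

VALID_FS = (200.0, 256.0, 512.0, 1024.0)


@dataclass
class Recording:
    """One patient's continuous multichannel recording.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz; one of 200, 256, 512, 1024.
    channel_labels : list of str
    electrode_xyz : ndarray, shape (n_channels, 3)
        Electrode coordinates in millimetres.
    start_time : datetime
        Absolute start of the recording.
    seizures : ndarray, shape (n_seizures, 2)
        Seizure (onset, offset) in seconds from recording start.
    soz_channels : list of str
        Subset of ``channel_labels`` in the seizure onset zone.
    hour_boundaries : ndarray, shape (n_hours, 2), optional
        Spans (seconds from start) of contiguous hour-long segments.  By
        default, consecutive full hours from t=0; a trailing partial hour
        is dropped.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    electrode_xyz: np.ndarray
    start_time: _dt.datetime
    seizures: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    soz_channels: list[str] = field(default_factory=list)
    hour_boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if float(self.fs) not in VALID_FS:
            raise ValueError(f"fs must be one of {VALID_FS}, got {self.fs}")
        self.fs = float(self.fs)
        self.electrode_xyz = np.asarray(self.electrode_xyz, dtype=float)
        if self.electrode_xyz.shape != (self.n_channels, 3):
            raise ValueError("electrode_xyz must be (n_channels, 3)")
        if not np.all(np.isfinite(self.electrode_xyz)):
            raise ValueError("electrode coordinates must be finite")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")
        self.seizures = np.asarray(self.seizures, dtype=float).reshape(-1, 2)
        if self.seizures.size:
            if self.seizures.min() < 0 or self.seizures.max() > self.duration_s:
                raise ValueError("seizure times must lie within the recording span")
            if np.any(self.seizures[:, 1] < self.seizures[:, 0]):
                raise ValueError("seizure offset precedes onset")
        unknown = set(self.soz_channels) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"soz_channels not in channel_labels: {sorted(unknown)}")
        if self.hour_boundaries is None:
            n_hours = int(self.duration_s // 3600)
            starts = 3600.0 * np.arange(n_hours)
            self.hour_boundaries = np.column_stack([starts, starts + 3600.0])
        else:
            self.hour_boundaries = np.asarray(self.hour_boundaries, dtype=float).reshape(-1, 2)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def soz_mask(self) -> np.ndarray:
        soz = set(self.soz_channels)
        return np.array([lab in soz for lab in self.channel_labels], dtype=bool)

    def with_signal(self, signal: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with a new signal array (same metadata)."""
        return replace(self, signal=signal, fs=self.fs if fs is None else fs)


# ---------------------------------------------------------------------------
# internal HDF5 container
# ---------------------------------------------------------------------------

def write_h5(path, rec: Recording) -> None:
    """Write a recording to the internal HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype(np.float32))
        f.create_dataset("fs", data=rec.fs)
        labels = np.array(rec.channel_labels, dtype=h5py.string_dtype())
        f.create_dataset("channel_labels", data=labels)
        f.create_dataset("electrode_xyz", data=rec.electrode_xyz)
        f.create_dataset("seizures", data=rec.seizures)
        f.create_dataset("soz_mask", data=rec.soz_mask.astype(np.uint8))
        f.create_dataset("hour_boundaries", data=rec.hour_boundaries)
        f.attrs["start_time"] = rec.start_time.isoformat()


def read_h5(path) -> Recording:
    """Read a recording from the internal HDF5 layout."""
    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_labels"][()]]
        soz_mask = f["soz_mask"][()].astype(bool)
        return Recording(
            signal=f["signal"][()].astype(float),
            fs=float(f["fs"][()]),
            channel_labels=labels,
            electrode_xyz=f["electrode_xyz"][()],
            start_time=_dt.datetime.fromisoformat(f.attrs["start_time"]),
            seizures=f["seizures"][()],
            soz_channels=[lab for lab, m in zip(labels, soz_mask) if m],
            hour_boundaries=f["hour_boundaries"][()],
        )


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit continuous recordings
# ---------------------------------------------------------------------------
# Minimal reader/writer for standard EDF with identical sampling rate on all
# channels and 1-second data records.  EDF carries no seizure annotations or
# electrode coordinates; those are supplied separately when constructing a
# Recording from an EDF file.

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, signal: np.ndarray, fs: float, channel_labels: list[str],
              start_time: _dt.datetime | None = None) -> None:
    """Write a multichannel signal (microvolts) as 16-bit EDF.

    ``fs`` must be an integer (1-second data records).  The signal is
    truncated to a whole number of records.
    """
    signal = np.asarray(signal, dtype=float)
    n_ch, n_samp = signal.shape
    fs_i = int(fs)
    if fs_i != fs:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = n_samp // fs_i
    if n_rec < 1:
        raise ValueError("signal shorter than one EDF data record")
    if start_time is None:
        start_time = _dt.datetime(2000, 1, 1)
    phys_min = np.floor(signal.min(axis=1))
    phys_max = np.ceil(signal.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(start_time.strftime("%d.%m.%y"), 8),
        _pad(start_time.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    sig_hdr = b"".join([
        b"".join(_pad(lab, 16) for lab in channel_labels),
        b"".join(_pad("iEEG", 80) for _ in range(n_ch)),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_pad(f"{phys_min[c]:g}", 8) for c in range(n_ch)),
        b"".join(_pad(f"{phys_max[c]:g}", 8) for c in range(n_ch)),
        b"".join(_pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(fs_i), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ])
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_hdr)
        for r in range(n_rec):
            chunk = signal[:, r * fs_i:(r + 1) * fs_i]
            dig = np.round((chunk - offset[:, None]) / gain[:, None])
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())


def read_edf(path):
    """Read a standard 16-bit EDF file.

    Returns ``(signal, fs, channel_labels, start_time)`` with the signal in
    physical units.  Requires all channels to share one sampling rate.
    """
    with open(path, "rb") as f:
        hdr = f.read(256)
        startdate = hdr[168:176].decode("ascii").strip()
        starttime = hdr[176:184].decode("ascii").strip()
        n_rec = int(hdr[236:244])
        rec_dur = float(hdr[244:252])
        n_ch = int(hdr[252:256])
        sig_hdr = f.read(256 * n_ch)

        def fields(off, width):
            base = off * n_ch
            return [sig_hdr[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(n_ch)]

        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("EDF reader supports a single sampling rate only")
        fs = spr[0] / rec_dur
        raw = np.frombuffer(f.read(), dtype="<i2")
    raw = raw[: n_rec * sum(spr)].reshape(n_rec, n_ch, spr[0])
    dig = raw.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    signal = dig * gain[:, None] + offset[:, None]
    day, month, year = (int(x) for x in startdate.split("."))
    hh, mm, ss = (int(x) for x in starttime.split("."))
    year += 2000 if year < 85 else 1900
    start = _dt.datetime(year, month, day, hh, mm, ss)
    return signal, fs, labels, start
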