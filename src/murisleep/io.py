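"""Reading and writing recordings, schedules and hypnograms.

Signals travel as two-channel (EEG, nuchal EMG) recordings in microvolts.
Two containers are supported: EDF (read via :mod:`mne`, written by a
minimal built-in 16-bit EDF writer) and a plain-text CSV dialect with a
``# fs=<Hz> start=<HH:MM:SS>`` header line and ``eeg_uV, emg_uV`` columns.
Hypnograms round-trip through CSV.
"""
from __future__ import annotations

import datetime as _dt
import io as _io
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .hypnogram import DARK, LIGHT, Hypnogram

#: Minimum sampling rate (Hz) able to resolve the 0.5–30 Hz EEG analysis
#: band and the EMG amplitude envelope.
MIN_FS = 60.0

_DAY_S = 86400.0


def parse_clock(value: str | float | _dt.time) -> float:
    """Convert a time-of-day (``"HH:MM:SS"``, :class:`datetime.time`, or
    seconds since midnight) to seconds since midnight in ``[0, 86400)``."""
    if isinstance(value, _dt.time):
        return value.hour * 3600 + value.minute * 60 + value.second + value.microsecond / 1e6
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) not in (2, 3):
            raise ValidationError(f"cannot parse clock time {value!r}")
        h, m = int(parts[0]), int(parts[1])
        s = float(parts[2]) if len(parts) == 3 else 0.0
        return (h * 3600 + m * 60 + s) % _DAY_S
    return float(value) % _DAY_S


def format_clock(seconds: float) -> str:
    seconds = seconds % _DAY_S
    h = int(seconds // 3600)
    m = int(seconds % 3600 // 60)
    s = seconds % 60
    return f"{h:02d}:{m:02d}:{s:06.3f}" if s % 1 else f"{h:02d}:{m:02d}:{int(s):02d}"


@dataclass
class LightSchedule:
    """A 12:12-h light-dark housing schedule.

    ``lights_on``/``lights_off`` are clock times; the two must be 12 h
    apart (modulo 24 h) so that every instant maps to exactly one phase.
    """

    lights_on: float = 6 * 3600.0
    lights_off: float = 18 * 3600.0

    def __post_init__(self) -> None:
        self.lights_on = parse_clock(self.lights_on)
        self.lights_off = parse_clock(self.lights_off)
        if abs((self.lights_off - self.lights_on) % _DAY_S - _DAY_S / 2) > 1e-6:
            raise ValidationError("lights_off must be 12 h after lights_on (mod 24 h)")

    def phase_at(self, clock_s: float) -> str:
        """Phase (``"L"`` or ``"D"``) containing the given time of day."""
        return LIGHT if (clock_s - self.lights_on) % _DAY_S < _DAY_S / 2 else DARK


@dataclass
class Recording:
    """A two-channel EEG/EMG recording in microvolts.

    Invariants: equal channel lengths, ``fs >= 60`` Hz, no NaN samples.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_clock: float = 0.0
    schedule: LightSchedule | None = field(default=None)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.start_clock = parse_clock(self.start_clock)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValidationError("channels must be one-dimensional sample series")
        if self.eeg.size != self.emg.size:
            raise FormatError(
                f"inconsistent channel lengths: eeg={self.eeg.size}, emg={self.emg.size}"
            )
        if self.fs < MIN_FS:
            raise ValidationError(f"sampling rate {self.fs} Hz below minimum {MIN_FS} Hz")
        if np.isnan(self.eeg).any() or np.isnan(self.emg).any():
            raise ValidationError("NaN samples after ingestion (gaps are an ingestion error)")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.eeg.size / self.fs

    def n_epochs(self, epoch_s: float = 10.0) -> int:
        """Number of whole scoring epochs (trailing partial epoch dropped)."""
        return int(self.duration // epoch_s)


def label_epochs_light_dark(
    n_epochs: int,
    epoch_s: float,
    start_clock: str | float,
    schedule: LightSchedule,
) -> np.ndarray:
    """Label each epoch LIGHT/DARK by the phase containing its start.

    ``epoch_s`` must divide 3600 s so epochs stay aligned to the clock.
    """
    if n_epochs < 1:
        raise ValidationError("need at least one epoch")
    if abs(3600 / epoch_s - round(3600 / epoch_s)) > 1e-9:
        raise ValidationError(f"epoch_s={epoch_s} must divide 3600 s")
    start = parse_clock(start_clock)
    onsets = (start + np.arange(n_epochs) * epoch_s) % _DAY_S
    in_light = (onsets - schedule.lights_on) % _DAY_S < _DAY_S / 2
    return np.where(in_light, LIGHT, DARK).astype("<U1")


# ---------------------------------------------------------------------------
# CSV signal container
# ---------------------------------------------------------------------------

def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording in the two-column CSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs:g} start={format_clock(rec.start_clock)}\n")
        fh.write("eeg_uV,emg_uV\n")
        np.savetxt(fh, np.column_stack([rec.eeg, rec.emg]), fmt="%.6f", delimiter=",")


def _read_recording_csv(path: Path) -> Recording:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError("CSV must start with a '# fs=<Hz> start=<HH:MM:SS>' header line")
        meta = dict(
            tok.split("=", 1) for tok in header.lstrip("#").split() if "=" in tok
        )
        if "fs" not in meta:
            raise FormatError("CSV header missing fs=<Hz>")
        fs = float(meta["fs"])
        start = meta.get("start", "00:00:00")
        df = pd.read_csv(fh)
    missing = {"eeg_uV", "emg_uV"} - set(df.columns)
    if missing:
        raise FormatError(f"CSV missing required column(s): {sorted(missing)}")
    return Recording(df["eeg_uV"].to_numpy(), df["emg_uV"].to_numpy(), fs=fs, start_clock=start)


# ---------------------------------------------------------------------------
# EDF container
# ---------------------------------------------------------------------------

def _pick_channel(names: list[str], wanted: str | None, keyword: str) -> int:
    if wanted is not None:
        for i, n in enumerate(names):
            if n.strip().lower() == wanted.strip().lower():
                return i
        raise FormatError(f"channel {wanted!r} not found among {names}")
    for i, n in enumerate(names):
        if keyword in n.lower():
            return i
    raise FormatError(f"no channel labelled like {keyword!r} among {names}")


def _read_recording_edf(
    path: Path, eeg_channel: str | None, emg_channel: str | None
) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    i_eeg = _pick_channel(names, eeg_channel, "eeg")
    i_emg = _pick_channel(names, emg_channel, "emg")
    data = raw.get_data()  # volts for dimensioned channels
    start = raw.info["meas_date"]
    start_s = 0.0
    if start is not None:
        start_s = start.hour * 3600 + start.minute * 60 + start.second
    return Recording(
        data[i_eeg] * 1e6,
        data[i_emg] * 1e6,
        fs=float(raw.info["sfreq"]),
        start_clock=start_s,
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    eeg_channel: str | None = None,
    emg_channel: str | None = None,
) -> Recording:
    """Read a two-channel recording from EDF or headered CSV.

    ``format`` is inferred from the file extension when not given.
    EDF amplitudes are converted to microvolts using the container's
    declared physical dimension.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        return _read_recording_edf(path, eeg_channel, emg_channel)
    raise ValidationError(f"unknown format {format!r}")


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    A deliberately small writer (the standard readers are far more
    featureful than any writer this pipeline needs): two channels labelled
    ``EEG``/``EMG``, physical dimension µV, per-channel linear scaling.
    Truncates to whole 1-s records; requires an integer sampling rate.
    """
    if rec.fs != int(rec.fs):
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(rec.fs)
    n_rec = int(rec.eeg.size // fs)
    if n_rec < 1:
        raise ValidationError("recording shorter than one 1-s EDF record")
    chans = [("EEG", rec.eeg[: n_rec * fs]), ("EMG", rec.emg[: n_rec * fs])]

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    start = rec.start_clock
    hh, mm, ss = int(start // 3600), int(start % 3600 // 60), int(start % 60)
    buf = _io.BytesIO()
    buf.write(pad("0", 8))
    buf.write(pad("X X X X", 80))
    buf.write(pad("Startdate 01-JAN-2000 X X X", 80))
    buf.write(pad("01.01.00", 8))
    buf.write(pad(f"{hh:02d}.{mm:02d}.{ss:02d}", 8))
    buf.write(pad(str(256 * (1 + 2)), 8))
    buf.write(pad("", 44))
    buf.write(pad(str(n_rec), 8))
    buf.write(pad("1", 8))
    buf.write(pad("2", 4))

    phys_ranges = []
    for _, sig in chans:
        amp = float(np.max(np.abs(sig))) if sig.size else 1.0
        amp = max(amp, 1.0)
        phys_ranges.append(amp)

    for label, _ in chans:
        buf.write(pad(label, 16))
    for _ in chans:
        buf.write(pad("", 80))
    for _ in chans:
        buf.write(pad("uV", 8))
    for amp in phys_ranges:
        buf.write(pad(f"{-amp:.6g}"[:8], 8))
    for amp in phys_ranges:
        buf.write(pad(f"{amp:.6g}"[:8], 8))
    for _ in chans:
        buf.write(pad("-32768", 8))
    for _ in chans:
        buf.write(pad("32767", 8))
    for _ in chans:
        buf.write(pad("", 80))
    for _ in chans:
        buf.write(pad(str(fs), 8))
    for _ in chans:
        buf.write(pad("", 32))

    digital = []
    for (_, sig), amp in zip(chans, phys_ranges):
        # EDF readers reconstruct phys = a + b*(dig - dmin); use symmetric scaling
        scaled = np.clip(np.round(sig / amp * 32767), -32768, 32767).astype("<i2")
        digital.append(scaled.reshape(n_rec, fs))
    for r in range(n_rec):
        for d in digital:
            buf.write(struct.pack(f"<{fs}h", *d[r]))
    Path(path).write_bytes(buf.getvalue())


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as CSV (epoch_index, start_s, stage, phase)."""
    if len(hyp) < 1:  # pragma: no cover - Hypnogram enforces this too
        raise ValidationError("empty hypnogram")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# epoch_s={hyp.epoch_s:g}\n")
        hyp.to_frame().to_csv(fh, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram written by :func:`write_hypnogram`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "epoch_s=" not in header:
            raise FormatError("hypnogram CSV must start with '# epoch_s=<s>'")
        epoch_s = float(header.split("epoch_s=")[1].split()[0])
        df = pd.read_csv(fh, keep_default_na=False)
    if "stage" not in df.columns:
        raise FormatError("hypnogram CSV missing 'stage' column")
    phase = None
    if "phase" in df.columns and (df["phase"].astype(str) != "").all():
        phase = df["phase"].to_numpy(dtype="<U1")
    return Hypnogram(df["stage"].to_numpy(dtype="<U1"), epoch_s=epoch_s, phase=phase)
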