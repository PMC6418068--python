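"""Signal conditioning and per-epoch spectral features.

Staging consumes four features per 10-s epoch: EEG band powers in the
delta (0.5–4.0 Hz), theta (6.0–9.0 Hz) and sigma (10.0–14.0 Hz) bands from
a Hann-windowed periodogram, and the moving-average amplitude of the
rectified EMG.  Band power is the integral of the one-sided power spectral
density over the bins whose centres fall in the closed band, so Parseval's
identity holds: summing over all bins recovers the epoch's mean square.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .io import LightSchedule, Recording, label_epochs_light_dark

logger = logging.getLogger(__name__)

#: Scoring bands (Hz), closed intervals.
DELTA = (0.5, 4.0)
THETA = (6.0, 9.0)
SIGMA = (10.0, 14.0)

#: Conditioning pass-bands (Hz).
EEG_BAND = (0.1, 30.0)
EMG_BAND = (10.0, 100.0)

FEATURE_COLUMNS = ["epoch_index", "start_s", "delta", "theta", "sigma", "emg_amp", "phase"]


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def condition_signals(
    rec: Recording,
    eeg_band: tuple[float, float] = EEG_BAND,
    emg_band: tuple[float, float] = EMG_BAND,
) -> Recording:
    """Band-pass the channels (EEG 0.1–30 Hz, EMG 10–100 Hz), zero-phase.

    Zero-phase (forward-backward) filtering preserves epoch alignment.
    When the sampling rate cannot support the requested EMG upper corner,
    the corner is capped at 0.45·fs with a logged warning.
    """
    if eeg_band[1] >= rec.fs / 2:
        raise ValidationError(
            f"fs={rec.fs} Hz too low for EEG band upper corner {eeg_band[1]} Hz"
        )
    emg_hi = emg_band[1]
    if emg_hi >= 0.45 * rec.fs:
        emg_hi = 0.45 * rec.fs
        logger.warning(
            "EMG upper corner %.1f Hz exceeds 0.45*fs; capped at %.1f Hz", emg_band[1], emg_hi
        )
    if emg_band[0] >= emg_hi:
        raise ValidationError(f"fs={rec.fs} Hz too low for EMG band {emg_band}")
    eeg = sps.sosfiltfilt(_bandpass_sos(*eeg_band, rec.fs), rec.eeg)
    emg = sps.sosfiltfilt(_bandpass_sos(emg_band[0], emg_hi, rec.fs), rec.emg)
    return Recording(eeg, emg, fs=rec.fs, start_clock=rec.start_clock, schedule=rec.schedule)


def _epoch_matrix(x: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    """Reshape a sample series into whole epochs, dropping the partial tail."""
    spe = int(round(fs * epoch_s))
    n = x.size // spe
    if n < 1:
        raise ValidationError("recording shorter than one epoch")
    return x[: n * spe].reshape(n, spe)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not mask.any():
        raise ValidationError(f"band {band} contains no frequency bins")
    return mask


def band_power(
    epoch_samples: np.ndarray,
    fs: float,
    band: tuple[float, float],
    window: str = "hann",
) -> float | np.ndarray:
    """Periodogram power (µV²) in the closed band ``[f_lo, f_hi]``.

    Accepts a single epoch (1-D) or a stack of epochs (2-D, epochs along
    the first axis); returns a scalar or a vector accordingly.
    """
    x = np.asarray(epoch_samples, dtype=float)
    if band[1] > fs / 2 + 1e-12:
        raise ValidationError(f"band upper edge {band[1]} Hz above Nyquist {fs / 2} Hz")
    freqs, pxx = sps.periodogram(x, fs=fs, window=window, axis=-1, scaling="density")
    df = freqs[1] - freqs[0]
    mask = _band_mask(freqs, band)
    out = pxx[..., mask].sum(axis=-1) * df
    return float(out) if out.ndim == 0 else out


def emg_amplitude(
    epoch_samples: np.ndarray,
    fs: float,
    window_s: float = 1.0,
) -> float | np.ndarray:
    """Mean over the epoch of the moving average of the rectified EMG (µV).

    The moving-average window (default 1 s) is the standard smoothing for
    nuchal muscle tone; it must not exceed the epoch length.
    """
    x = np.abs(np.asarray(epoch_samples, dtype=float))
    win = int(round(window_s * fs))
    if win < 1 or win > x.shape[-1]:
        raise ValidationError("moving-average window must be within (0, epoch length]")
    smoothed = uniform_filter1d(x, size=win, axis=-1, mode="nearest")
    out = smoothed.mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def featurize(
    rec: Recording,
    epoch_s: float = 10.0,
    schedule: LightSchedule | None = None,
    window: str = "hann",
    emg_window_s: float = 1.0,
) -> pd.DataFrame:
    """Per-epoch feature table: delta/theta/sigma band powers, EMG amplitude.

    One row per whole epoch (a trailing partial epoch is dropped), with a
    LIGHT/DARK phase label when a schedule is available.
    """
    schedule = schedule if schedule is not None else rec.schedule
    eeg = _epoch_matrix(rec.eeg, rec.fs, epoch_s)
    emg = _epoch_matrix(rec.emg, rec.fs, epoch_s)
    n = eeg.shape[0]
    table = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "start_s": np.arange(n) * epoch_s,
            "delta": band_power(eeg, rec.fs, DELTA, window=window),
            "theta": band_power(eeg, rec.fs, THETA, window=window),
            "sigma": band_power(eeg, rec.fs, SIGMA, window=window),
            "emg_amp": emg_amplitude(emg, rec.fs, window_s=emg_window_s),
        }
    )
    if schedule is not None:
        table["phase"] = label_epochs_light_dark(n, epoch_s, rec.start_clock, schedule)
    else:
        table["phase"] = ""
    return table
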