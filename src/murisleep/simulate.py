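"""Synthetic rodent polysomnography with known ground truth.

The generator has two layers.  A semi-Markov chain produces the truth
hypnogram: bout lengths are geometric at epoch resolution (memoryless
within a state) with per-state mean durations on the scale reported for
mice (NREM ~4.5 min, REM ~1.1 min), transitions follow standard rodent
architecture (WAKE -> NREM, NREM -> {REM, WAKE}, REM -> {WAKE, NREM};
never WAKE -> REM), and the dark phase lengthens wake bouts by a
configurable factor.  On top of the hypnogram, EEG is synthesised as a sum
of band-limited Gaussian noise components (zero-phase spectral-mask
filters, so expected in-band power equals the configured per-state target
exactly) plus a broadband floor, and EMG as 10-100 Hz Gaussian noise whose
rectified-mean amplitude matches the per-state target.  State changes are
crossfaded over ~1 s so the signals stay continuous across epoch
boundaries.  Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .hypnogram import NREM, REM, WAKE, Hypnogram
from .io import LightSchedule, Recording, label_epochs_light_dark

#: (delta, theta, sigma) band-power targets in µV² per state.  NREM is
#: delta-dominant, REM theta-dominant, WAKE mixed and low-amplitude.
DEFAULT_BAND_POWER = {
    WAKE: (30.0, 30.0, 15.0),
    NREM: (200.0, 50.0, 40.0),
    REM: (30.0, 90.0, 15.0),
}
#: Rectified-mean EMG amplitude targets (µV): high in wake, atonia in REM.
DEFAULT_EMG_AMP = {WAKE: 25.0, NREM: 8.0, REM: 3.0}

_BANDS = ((0.5, 4.0), (6.0, 9.0), (10.0, 14.0))


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Bout-duration means are in minutes; ``dark_wake_factor`` multiplies the
    wake mean for bouts starting in the dark (nocturnal activity).  Band
    powers are µV² targets per state, the EMG target is the rectified-mean
    amplitude in µV, and ``noise_floor`` is a flat broadband EEG floor in
    µV²/Hz.  Signal amplitudes are arbitrary-but-configurable: the staging
    method is scale-free once calibrated.
    """

    seed: int = 0
    hours: float = 24.0
    epoch_s: float = 10.0
    fs: float = 300.0
    lights_on: str | float = "06:00:00"
    start_clock: str | float | None = None  # default: recording starts at lights-on
    wake_bout_min: float = 3.8
    nrem_bout_min: float = 4.5
    rem_bout_min: float = 1.1
    dark_wake_factor: float = 1.5
    p_nrem_to_rem: float = 0.5
    p_rem_to_wake: float = 0.5
    band_power: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_BAND_POWER.items()})
    emg_amp: dict = field(default_factory=lambda: dict(DEFAULT_EMG_AMP))
    noise_floor: float = 0.05
    crossfade_s: float = 1.0

    def __post_init__(self) -> None:
        if self.hours <= 0 or self.epoch_s <= 0 or self.fs < 60:
            raise ValidationError("hours and epoch_s must be positive, fs >= 60 Hz")
        for name in ("wake_bout_min", "nrem_bout_min", "rem_bout_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive (inf allowed for wake)")
        for p in (self.p_nrem_to_rem, self.p_rem_to_wake):
            if not 0 <= p <= 1:
                raise ValidationError("transition probabilities must lie in [0, 1]")
        bp = self.band_power
        if not bp[NREM][0] > bp[WAKE][0]:
            raise ValidationError("NREM delta power must exceed WAKE delta power")
        if not bp[REM][1] / bp[REM][0] > bp[NREM][1] / bp[NREM][0]:
            raise ValidationError("REM theta/delta ratio must exceed NREM's")
        e = self.emg_amp
        if not e[WAKE] > e[NREM] > e[REM]:
            raise ValidationError("EMG amplitude must order WAKE > NREM > REM")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be non-negative")

    @property
    def schedule(self) -> LightSchedule:
        on = self.lights_on
        return LightSchedule(lights_on=on)

    def mean_bout_epochs(self, state: str, phase: str = "L") -> float:
        minutes = {WAKE: self.wake_bout_min, NREM: self.nrem_bout_min, REM: self.rem_bout_min}[state]
        if state == WAKE and phase == "D":
            minutes = minutes * self.dark_wake_factor
        return minutes * 60.0 / self.epoch_s


def separated_config(**overrides) -> SimConfig:
    """Conditions with essentially non-overlapping state distributions,
    for verifying that staging accuracy approaches 100% at high SNR."""
    cfg = SimConfig(
        band_power={
            WAKE: (10.0, 10.0, 5.0),
            NREM: (500.0, 25.0, 60.0),
            REM: (10.0, 200.0, 5.0),
        },
        emg_amp={WAKE: 60.0, NREM: 5.0, REM: 0.5},
        noise_floor=0.01,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class LabelledRecording:
    """A synthetic recording together with its generator-truth hypnogram."""

    recording: Recording | None
    truth: Hypnogram
    group: str | None = None


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def sample_hypnogram(cfg: SimConfig) -> Hypnogram:
    """Draw a truth hypnogram from the semi-Markov architecture model."""
    n = int(round(cfg.hours * 3600 / cfg.epoch_s))
    if n < 1:
        raise ValidationError("configuration yields no whole epochs")
    start = cfg.start_clock if cfg.start_clock is not None else cfg.lights_on
    phase = label_epochs_light_dark(n, cfg.epoch_s, start, cfg.schedule)
    rng = _rng(cfg, 0)
    stages = np.empty(n, dtype="<U1")
    pos = 0
    state = WAKE
    while pos < n:
        mean = cfg.mean_bout_epochs(state, phase[pos])
        if np.isinf(mean):
            stages[pos:] = state
            break
        length = int(rng.geometric(min(1.0, 1.0 / max(mean, 1.0))))
        end = min(pos + length, n)
        stages[pos:end] = state
        pos = end
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < cfg.p_nrem_to_rem else WAKE
        else:
            state = WAKE if rng.random() < cfg.p_rem_to_wake else NREM
    return Hypnogram(stages, epoch_s=cfg.epoch_s, phase=phase)


def stationary_fractions(cfg: SimConfig, phase: str = "L") -> dict[str, float]:
    """Analytic long-run state fractions of the semi-Markov chain.

    Visit rates per cycle solve the balance equations (one NREM visit per
    wake visit plus REM->NREM re-entries); time fractions weight visits by
    mean bout length for the given phase.
    """
    v_n = 1.0
    v_r = cfg.p_nrem_to_rem
    v_w = (1.0 - cfg.p_nrem_to_rem) + cfg.p_nrem_to_rem * cfg.p_rem_to_wake
    times = {
        NREM: v_n * cfg.mean_bout_epochs(NREM, phase),
        REM: v_r * cfg.mean_bout_epochs(REM, phase),
        WAKE: v_w * cfg.mean_bout_epochs(WAKE, phase),
    }
    total = sum(times.values())
    return {s: t / total for s, t in times.items()}


def _unit_band_noise(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Gaussian noise band-limited by a zero-phase spectral mask, unit variance."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    freqs = rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    track = irfft(spec, n=n)
    sd = track.std()
    return track / sd if sd > 0 else track


def _state_gain(
    per_state: dict[str, float], stages: np.ndarray, spe: int, smooth: int
) -> np.ndarray:
    g = np.repeat([per_state[s] for s in stages], spe)
    if smooth > 1:
        g = uniform_filter1d(g, size=smooth, mode="nearest")
    return g


def synthesize_signals(hyp: Hypnogram, cfg: SimConfig) -> LabelledRecording:
    """Render state-conditioned EEG/EMG for a (truth) hypnogram."""
    if len(hyp) < 1:
        raise ValidationError("empty hypnogram")
    spe = int(round(cfg.fs * hyp.epoch_s))
    n = spe * len(hyp)
    rng = _rng(cfg, 1)
    smooth = max(1, int(round(cfg.crossfade_s * cfg.fs)))

    eeg = np.zeros(n)
    for b, band in enumerate(_BANDS):
        targets = {s: np.sqrt(cfg.band_power[s][b]) for s in cfg.band_power}
        if all(t == 0 for t in targets.values()):
            continue
        track = _unit_band_noise(rng, n, cfg.fs, band)
        eeg += track * _state_gain(targets, hyp.stages, spe, smooth)
    if cfg.noise_floor > 0:
        eeg += rng.standard_normal(n) * np.sqrt(cfg.noise_floor * cfg.fs / 2.0)

    emg_band = (10.0, min(100.0, 0.45 * cfg.fs))
    emg_track = _unit_band_noise(rng, n, cfg.fs, emg_band)
    # rectified mean of N(0, s^2) is s*sqrt(2/pi); invert to hit the target
    emg_targets = {s: a * np.sqrt(np.pi / 2.0) for s, a in cfg.emg_amp.items()}
    emg = emg_track * _state_gain(emg_targets, hyp.stages, spe, smooth)

    start = cfg.start_clock if cfg.start_clock is not None else cfg.lights_on
    rec = Recording(eeg, emg, fs=cfg.fs, start_clock=start, schedule=cfg.schedule)
    return LabelledRecording(recording=rec, truth=hyp)


def generate_cohort(
    n_per_group: int,
    cfg_a: SimConfig,
    cfg_b: SimConfig,
    master_seed: int | None = None,
    groups: tuple[str, str] = ("A", "B"),
    signals: bool = True,
) -> list[LabelledRecording]:
    """Simulate two groups of animals with reproducible per-animal seeds.

    With ``signals=False`` only truth hypnograms are generated (fast path
    for architecture-level studies).
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if master_seed is None:
        master_seed = cfg_a.seed
    words = np.random.SeedSequence(int(master_seed)).generate_state(2 * n_per_group)
    cohort: list[LabelledRecording] = []
    for g, cfg in zip(groups, (cfg_a, cfg_b)):
        for i in range(n_per_group):
            seed = int(words[len(cohort)] & 0x7FFFFFFF)
            animal_cfg = replace(cfg, seed=seed)
            hyp = sample_hypnogram(animal_cfg)
            if signals:
                lab = synthesize_signals(hyp, animal_cfg)
            else:
                lab = LabelledRecording(recording=None, truth=hyp)
            lab.group = g
            cohort.append(lab)
    return cohort
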