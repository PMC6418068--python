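"""murisleep: rodent EEG/EMG sleep-architecture analysis.

A pipeline for staging 10-s epochs of two-channel (EEG, nuchal EMG)
rodent polysomnography into WAKE/NREM/REM via spectral band-power
thresholds, segmenting the hypnogram into bouts, scoring arousals and
sleep latencies, and summarising sleep architecture over 24-h and 12-h
light/dark windows — together with a synthetic generator that makes every
stage verifiable without animal data.
"""

from .bouts import (
    Bout,
    EventSet,
    arousal_frequency,
    detect_arousals,
    segment_bouts,
    time_to_resume_sleep,
)
from .errors import (
    CalibrationError,
    FormatError,
    MurisleepError,
    UndefinedMetricError,
    ValidationError,
)
from .features import band_power, condition_signals, emg_amplitude, featurize
from .hypnogram import DARK, LIGHT, NREM, REM, STAGES, WAKE, Hypnogram
from .io import (
    LightSchedule,
    Recording,
    label_epochs_light_dark,
    read_hypnogram,
    read_recording,
    write_hypnogram,
    write_recording_csv,
    write_recording_edf,
)
from .simulate import (
    LabelledRecording,
    SimConfig,
    generate_cohort,
    sample_hypnogram,
    separated_config,
    stationary_fractions,
    synthesize_signals,
)
from .staging import (
    StagingConfusion,
    ThresholdSet,
    classify_epochs,
    fit_thresholds,
    staging_confusion,
)
from .summary import (
    METRICS,
    GroupComparison,
    SleepSummary,
    compare_groups,
    report,
    summarize,
)

__version__ = "0.1.0"

__all__ = [
    "Bout",
    "EventSet",
    "arousal_frequency",
    "detect_arousals",
    "segment_bouts",
    "time_to_resume_sleep",
    "CalibrationError",
    "FormatError",
    "MurisleepError",
    "UndefinedMetricError",
    "ValidationError",
    "band_power",
    "condition_signals",
    "emg_amplitude",
    "featurize",
    "DARK",
    "LIGHT",
    "NREM",
    "REM",
    "STAGES",
    "WAKE",
    "Hypnogram",
    "LightSchedule",
    "Recording",
    "label_epochs_light_dark",
    "read_hypnogram",
    "read_recording",
    "write_hypnogram",
    "write_recording_csv",
    "write_recording_edf",
    "LabelledRecording",
    "SimConfig",
    "generate_cohort",
    "sample_hypnogram",
    "separated_config",
    "stationary_fractions",
    "synthesize_signals",
    "StagingConfusion",
    "ThresholdSet",
    "classify_epochs",
    "fit_thresholds",
    "staging_confusion",
    "METRICS",
    "GroupComparison",
    "SleepSummary",
    "compare_groups",
    "report",
    "summarize",
    "stage_recording",
]


def stage_recording(rec, epoch_s: float = 10.0, schedule=None, manual_thresholds=None):
    """Convenience end-to-end staging: condition, featurize, calibrate, classify.

    Returns ``(hypnogram, thresholds, features)``.
    """
    conditioned = condition_signals(rec)
    features = featurize(conditioned, epoch_s=epoch_s, schedule=schedule)
    thresholds = fit_thresholds(features, manual=manual_thresholds)
    hyp = classify_epochs(features, thresholds, epoch_s=epoch_s)
    return hyp, thresholds, features
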