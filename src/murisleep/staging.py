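"""Threshold-based three-state sleep staging.

Two scatter-plot rules classify each 10-s epoch.  First, sigma*theta
power is plotted against EMG amplitude and a straight line separates wake
(high EMG, low sigma*theta) from sleep; second, among sleep epochs the
delta/theta power ratio separates NREM (delta-dominant) from REM
(theta-dominant).

The original method set the line and the ratio threshold per 24-h record
without stating a procedure, so calibration is the one deliberately open
step here: the default fits a 2-component k-means to (log10 EMG,
log10 sigma*theta) and takes the perpendicular bisector of the cluster
centres as the sleep/wake line, then places the delta/theta threshold at
the antimode of log(delta/theta) over sleep-side epochs.  Every field can
be overridden manually.  Band powers are log-transformed for calibration
because they are strongly right-skewed; the fitted line lives in log10
space and classification applies it there.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .errors import CalibrationError, ValidationError
from .hypnogram import NREM, REM, STAGES, WAKE, Hypnogram

_EPS = 1e-12

#: Minimum number of epochs (1 h at 10 s) for stable automatic calibration.
MIN_CALIBRATION_EPOCHS = 360


@dataclass(frozen=True)
class ThresholdSet:
    """Decision thresholds for the two staging rules.

    The sleep/wake boundary is the line ``y = sw_slope * x + sw_intercept``
    in the plane ``x = log10(emg_amp)``, ``y = log10(sigma * theta)``;
    ``wake_side`` names the side of the line scored as wake.  Points on
    the line score as sleep (boundaries close toward sleep).
    ``dt_threshold`` is the raw delta/theta power ratio at or above which a
    sleep epoch scores NREM (the boundary closes toward NREM).
    """

    sw_slope: float
    sw_intercept: float
    dt_threshold: float
    wake_side: str = "below"

    def __post_init__(self) -> None:
        if not np.isfinite([self.sw_slope, self.sw_intercept, self.dt_threshold]).all():
            raise ValidationError("thresholds must be finite")
        if self.dt_threshold <= 0:
            raise ValidationError("dt_threshold must be positive")
        if self.wake_side not in ("above", "below"):
            raise ValidationError("wake_side must be 'above' or 'below'")

    def wake_score(self, log_emg: np.ndarray, log_st: np.ndarray) -> np.ndarray:
        """Signed distance-like score; positive strictly on the wake side."""
        s = log_st - (self.sw_slope * log_emg + self.sw_intercept)
        return s if self.wake_side == "above" else -s


def _log_features(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = np.log10(features["emg_amp"].to_numpy(float) + _EPS)
    y = np.log10(
        features["sigma"].to_numpy(float) * features["theta"].to_numpy(float) + _EPS
    )
    return x, y


def _antimode(z: np.ndarray) -> float:
    """Deepest density minimum between the two tallest modes of ``z``."""
    kde = gaussian_kde(z)
    grid = np.linspace(z.min(), z.max(), 512)
    dens = kde(grid)
    interior = np.arange(1, grid.size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if maxima.size < 2:
        raise CalibrationError(
            "log(delta/theta) density is unimodal; supply dt_threshold manually"
        )
    top2 = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    between = np.arange(top2[0], top2[1] + 1)
    return float(grid[between[np.argmin(dens[between])]])


def fit_thresholds(
    features: pd.DataFrame,
    manual: dict | None = None,
    random_state: int = 0,
) -> ThresholdSet:
    """Calibrate staging thresholds from a feature table.

    With no ``manual`` overrides, runs the automatic calibration described
    in the module docstring; a ``manual`` mapping may pin any subset of
    ``sw_slope``, ``sw_intercept``, ``wake_side``, ``dt_threshold`` (a full
    set skips calibration entirely).

    Raises :class:`CalibrationError` on degenerate input — near-zero
    feature variance, a single cluster, or a unimodal delta/theta ratio —
    in which case manual thresholds must be supplied.
    """
    manual = dict(manual or {})
    line_keys = {"sw_slope", "sw_intercept"}
    if line_keys | {"dt_threshold"} <= set(manual):
        return ThresholdSet(
            sw_slope=float(manual["sw_slope"]),
            sw_intercept=float(manual["sw_intercept"]),
            dt_threshold=float(manual["dt_threshold"]),
            wake_side=manual.get("wake_side", "below"),
        )

    if len(features) < MIN_CALIBRATION_EPOCHS:
        raise ValidationError(
            f"need >= {MIN_CALIBRATION_EPOCHS} epochs for calibration, got {len(features)}"
        )
    x, y = _log_features(features)
    pts = np.column_stack([x, y])
    if pts.std(axis=0).max() < 1e-9:
        raise CalibrationError("features have zero variance; supply manual thresholds")

    if line_keys <= set(manual):
        sw_slope = float(manual["sw_slope"])
        sw_intercept = float(manual["sw_intercept"])
        wake_side = manual.get("wake_side", "below")
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(pts)
        c0, c1 = km.cluster_centers_
        sep = float(np.linalg.norm(c1 - c0))
        spread = float(np.sqrt(km.inertia_ / len(pts)))
        if sep < 0.05 or sep < 0.5 * spread:
            raise CalibrationError(
                "sleep/wake clusters are not separable; supply manual thresholds"
            )
        # wake cluster = higher EMG centre; boundary = perpendicular bisector
        c_wake, c_sleep = (c0, c1) if c0[0] > c1[0] else (c1, c0)
        dx, dy = c_wake - c_sleep
        mid = (c_wake + c_sleep) / 2.0
        if abs(dy) < 1e-9:
            dy = np.sign(dy) * 1e-9 if dy != 0 else 1e-9
        sw_slope = -dx / dy
        sw_intercept = mid[1] - sw_slope * mid[0]
        wake_side = "above" if c_wake[1] - (sw_slope * c_wake[0] + sw_intercept) > 0 else "below"

    probe = ThresholdSet(sw_slope, sw_intercept, dt_threshold=1.0, wake_side=wake_side)
    sleep_mask = probe.wake_score(x, y) <= 0
    if "dt_threshold" in manual:
        dt = float(manual["dt_threshold"])
    else:
        if sleep_mask.sum() < 10:
            raise CalibrationError("too few sleep-side epochs to place dt_threshold")
        delta = features["delta"].to_numpy(float)[sleep_mask]
        theta = features["theta"].to_numpy(float)[sleep_mask]
        z = np.log(delta + _EPS) - np.log(theta + _EPS)
        dt = float(np.exp(_antimode(z)))
    return ThresholdSet(sw_slope, sw_intercept, dt_threshold=dt, wake_side=wake_side)


def classify_epochs(
    features: pd.DataFrame,
    th: ThresholdSet,
    epoch_s: float = 10.0,
) -> Hypnogram:
    """Stage every epoch: the wake rule first, then the delta/theta rule.

    An epoch strictly on the wake side of the line is WAKE regardless of
    its delta/theta ratio; otherwise it is NREM when delta/theta is at or
    above ``dt_threshold`` and REM below it.
    """
    x, y = _log_features(features)
    wake = th.wake_score(x, y) > 0
    delta = features["delta"].to_numpy(float)
    theta = features["theta"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(theta > 0, delta / np.where(theta > 0, theta, 1.0), np.inf)
    stages = np.where(wake, WAKE, np.where(ratio >= th.dt_threshold, NREM, REM))
    phase = None
    if "phase" in features.columns:
        ph = features["phase"].to_numpy(str)
        if (ph != "").all():
            phase = ph.astype("<U1")
    return Hypnogram(stages.astype("<U1"), epoch_s=epoch_s, phase=phase)


@dataclass
class StagingConfusion:
    """Confusion counts (rows = truth, columns = predicted) and recalls."""

    matrix: pd.DataFrame
    recall: dict[str, float]
    accuracy: float


def staging_confusion(predicted: Hypnogram, truth: Hypnogram) -> StagingConfusion:
    """Compare a predicted hypnogram against generator truth."""
    if len(predicted) != len(truth):
        raise ValidationError("hypnogram lengths differ")
    mat = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES), dtype=int)
    for t in STAGES:
        sel = predicted.stages[truth.stages == t]
        for p in STAGES:
            mat.loc[t, p] = int(np.sum(sel == p))
    totals = mat.sum(axis=1)
    recall = {
        s: float(mat.loc[s, s] / totals[s]) if totals[s] > 0 else float("nan")
        for s in STAGES
    }
    accuracy = float(np.trace(mat.to_numpy()) / len(truth))
    return StagingConfusion(matrix=mat, recall=recall, accuracy=accuracy)
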