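"""Per-epoch stage labels at fixed epoch resolution.

The hypnogram is the atomic result of sleep staging: one label per scoring
epoch (10 s by default), drawn from the three-state alphabet WAKE / NREM /
REM, optionally annotated with the light/dark phase of each epoch's start.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical single-letter stage codes.
WAKE = "W"
NREM = "N"
REM = "R"
STAGES = (WAKE, NREM, REM)

#: Phase codes for the light/dark cycle.
LIGHT = "L"
DARK = "D"

SLEEP_STAGES = frozenset({NREM, REM})


@dataclass
class Hypnogram:
    """Sequence of per-epoch sleep-stage labels.

    Parameters
    ----------
    stages
        One single-character label per epoch, each in ``{"W", "N", "R"}``.
    epoch_s
        Epoch length in seconds (default 10).
    phase
        Optional per-epoch light/dark label (``"L"``/``"D"``), same length
        as ``stages``.
    """

    stages: np.ndarray
    epoch_s: float = 10.0
    phase: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.stages = np.asarray(list(self.stages), dtype="<U1")
        if self.stages.size < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.stages)) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if self.phase is not None:
            self.phase = np.asarray(list(self.phase), dtype="<U1")
            if self.phase.shape != self.stages.shape:
                raise ValidationError("phase must have one label per epoch")
            badp = set(np.unique(self.phase)) - {LIGHT, DARK}
            if badp:
                raise ValidationError(f"unknown phase labels: {sorted(badp)}")

    def __len__(self) -> int:
        return int(self.stages.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        same_phase = (
            (self.phase is None and other.phase is None)
            or (
                self.phase is not None
                and other.phase is not None
                and np.array_equal(self.phase, other.phase)
            )
        )
        return (
            np.array_equal(self.stages, other.stages)
            and self.epoch_s == other.epoch_s
            and same_phase
        )

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    def string(self) -> str:
        """Stage labels as one string, e.g. ``"WWWNNNR"``."""
        return "".join(self.stages)

    def is_sleep(self) -> np.ndarray:
        """Boolean mask of sleep (NREM or REM) epochs."""
        return (self.stages == NREM) | (self.stages == REM)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: epoch_index, start_s, stage and phase columns."""
        n = len(self)
        return pd.DataFrame(
            {
                "epoch_index": np.arange(n),
                "start_s": np.arange(n) * self.epoch_s,
                "stage": self.stages,
                "phase": self.phase if self.phase is not None else [""] * n,
            }
        )

    def fraction(self, stage: str, mask: np.ndarray | None = None) -> float:
        """Fraction of (masked) epochs scored as ``stage``."""
        sel = self.stages if mask is None else self.stages[mask]
        if sel.size == 0:
            raise ValidationError("empty epoch selection")
        return float(np.mean(sel == stage))
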