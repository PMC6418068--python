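"""Bout segmentation, arousal detection and sleep-latency metrics.

The scoring rules operate on run lengths of the hypnogram:

* an NREM bout opens at the first epoch of a run of >= 3 consecutive NREM
  epochs and closes immediately before the first run of >= 3 consecutive
  wake epochs or >= 2 consecutive REM epochs;
* a REM bout opens at a run of >= 2 consecutive REM epochs and closes
  immediately before the first stretch of >= 3 consecutive non-REM epochs
  (wake and NREM pooled);
* a wake bout opens at a run of >= 3 consecutive wake epochs and closes
  immediately before the first stretch of >= 3 consecutive sleep epochs
  (any NREM/REM mix);
* an arousal is the first epoch of any maximal wake run immediately
  preceded by >= 3 consecutive sleep epochs;
* time to resume sleep runs from the onset of a wake run of >= 3 epochs to
  the start of the next stretch of >= 3 consecutive sleep epochs.

Segmentation is a single left-to-right scan: while a bout is open no other
bout can start, and a bout whose terminator never arrives closes at the
last epoch of its own state.  Brief intrusions (too short to terminate)
therefore fall inside the bout's span; both the span duration and the
number of own-state epochs are reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .hypnogram import DARK, LIGHT, NREM, REM, WAKE, Hypnogram

#: Minimum opening-run length per state (epochs).
OPEN_LEN = {NREM: 3, REM: 2, WAKE: 3}

#: Minimum terminator lengths (epochs).
TERM_WAKE_FOR_NREM = 3
TERM_REM_FOR_NREM = 2
TERM_POOLED = 3


@dataclass(frozen=True)
class Bout:
    """A maximal scored run of one state.

    ``start_epoch`` inclusive, ``end_epoch`` exclusive.  ``n_state_epochs``
    counts the epochs inside the span actually labelled with the bout's
    state (the span may contain intrusions too short to terminate it).
    """

    kind: str
    start_epoch: int
    end_epoch: int
    epoch_s: float = 10.0
    n_state_epochs: int = 0

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ValidationError("bout must span at least one epoch")

    @property
    def duration_min(self) -> float:
        return (self.end_epoch - self.start_epoch) * self.epoch_s / 60.0


@dataclass
class EventSet:
    """Arousal onsets, qualifying wake onsets and their resume latencies."""

    arousals: list[int] = field(default_factory=list)
    wake_onsets: list[int] = field(default_factory=list)
    resume_latencies: list[float] = field(default_factory=list)  # minutes
    epoch_s: float = 10.0


def _runs(labels: np.ndarray | str) -> list[tuple[str, int, int]]:
    """Run-length encode labels into (state, start, length) triples."""
    arr = np.asarray(list(labels), dtype="<U1")
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    return [(str(arr[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _pooled_block(runs, k, exclude_state):
    """Maximal stretch of consecutive runs not in ``exclude_state`` starting
    at run index ``k``; returns (start_epoch, total_len, next_run_index)."""
    total = 0
    start = runs[k][1]
    while k < len(runs) and runs[k][0] != exclude_state:
        total += runs[k][2]
        k += 1
    return start, total, k


def _find_terminator(runs, j, state):
    """Run index of the first terminator for a ``state`` bout open at run j."""
    if state == NREM:
        for k in range(j + 1, len(runs)):
            st, _, ln = runs[k]
            if (st == WAKE and ln >= TERM_WAKE_FOR_NREM) or (
                st == REM and ln >= TERM_REM_FOR_NREM
            ):
                return k
        return None
    # REM and WAKE bouts terminate on a pooled stretch of foreign states
    k = j + 1
    while k < len(runs):
        if runs[k][0] != state:
            _, total, nxt = _pooled_block(runs, k, state)
            if total >= TERM_POOLED:
                return k
            k = nxt
        else:
            k += 1
    return None


def segment_bouts(hyp: Hypnogram) -> list[Bout]:
    """Segment the hypnogram into NREM/REM/WAKE bouts (left-to-right scan).

    Epochs between a bout's close and the next bout's open belong to no
    bout.  Runs truncated by the record boundaries still qualify when
    their observed length meets the opening minimum.
    """
    runs = _runs(hyp.stages)
    bouts: list[Bout] = []
    i = 0
    while i < len(runs):
        j = next(
            (k for k in range(i, len(runs)) if runs[k][2] >= OPEN_LEN[runs[k][0]]),
            None,
        )
        if j is None:
            break
        state, start, _ = runs[j]
        term = _find_terminator(runs, j, state)
        if term is not None:
            end = runs[term][1]
            span_runs = runs[j:term]
            i = term
        else:
            last = max(k for k in range(j, len(runs)) if runs[k][0] == state)
            end = runs[last][1] + runs[last][2]
            span_runs = runs[j : last + 1]
            i = last + 1
        n_state = sum(ln for st, _, ln in span_runs if st == state)
        bouts.append(
            Bout(state, start, end, epoch_s=hyp.epoch_s, n_state_epochs=n_state)
        )
    return bouts


def detect_arousals(hyp: Hypnogram) -> list[int]:
    """Onset epochs of wake runs immediately preceded by >= 3 sleep epochs.

    Any NREM/REM mix counts toward the preceding sleep stretch; each
    maximal wake run yields at most one arousal.
    """
    runs = _runs(hyp.stages)
    arousals: list[int] = []
    for k, (state, start, _) in enumerate(runs):
        if state != WAKE or k == 0:
            continue
        preceding = 0
        for p in range(k - 1, -1, -1):
            if runs[p][0] == WAKE:
                break
            preceding += runs[p][2]
        if preceding >= TERM_POOLED:
            arousals.append(start)
    return arousals


def time_to_resume_sleep(hyp: Hypnogram) -> EventSet:
    """Latency from each qualifying wake onset to sustained sleep.

    A wake onset qualifies when its maximal wake run lasts >= 3 epochs;
    the latency runs to the first epoch of the next stretch of >= 3
    consecutive sleep epochs.  Onsets with no subsequent qualifying sleep
    stretch are excluded.  Arousal onsets are reported alongside.
    """
    runs = _runs(hyp.stages)
    sleep_starts = []  # starts of pooled sleep stretches of >= 3 epochs
    k = 0
    while k < len(runs):
        if runs[k][0] != WAKE:
            start, total, nxt = _pooled_block(runs, k, WAKE)
            if total >= TERM_POOLED:
                sleep_starts.append(start)
            k = nxt
        else:
            k += 1
    events = EventSet(epoch_s=hyp.epoch_s)
    events.arousals = detect_arousals(hyp)
    for state, start, ln in runs:
        if state != WAKE or ln < OPEN_LEN[WAKE]:
            continue
        nxt = next((q for q in sleep_starts if q > start), None)
        if nxt is None:
            continue
        events.wake_onsets.append(start)
        events.resume_latencies.append((nxt - start) * hyp.epoch_s / 60.0)
    return events


def _window_mask(hyp: Hypnogram, window: str) -> np.ndarray:
    if window == "H24":
        return np.ones(len(hyp), dtype=bool)
    if window in (LIGHT, DARK, "LIGHT", "DARK"):
        if hyp.phase is None:
            raise ValidationError("hypnogram has no light/dark phase labels")
        return hyp.phase == window[0]
    raise ValidationError(f"unknown window {window!r}")


def arousal_frequency(hyp: Hypnogram, window: str = "H24") -> float:
    """Arousals per hour of sleep within a window (H24, LIGHT or DARK).

    The numerator counts arousals whose onset epoch lies in the window;
    the denominator is the window's total sleep (NREM + REM) time in hours.
    """
    mask = _window_mask(hyp, window)
    sleep_h = (hyp.is_sleep() & mask).sum() * hyp.epoch_s / 3600.0
    if sleep_h <= 0:
        raise UndefinedMetricError(f"no sleep time in window {window!r}")
    n = sum(1 for a in detect_arousals(hyp) if mask[a])
    return n / sleep_h
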