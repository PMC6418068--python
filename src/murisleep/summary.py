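"""Per-animal sleep-architecture summaries and group comparisons.

Each animal yields one row of metrics per analysis window (the full day
plus the 12-h light and dark phases): state percentages from epoch
counts, NREM/REM bout counts and mean durations, arousals per hour of
sleep, and mean time to resume sleep.  Groups are compared metric-wise
with the unpaired two-tailed Student's t test (pooled variance,
df = n_a + n_b - 2), reported as mean ± SEM.  No multiple-testing
correction is applied by default; Holm-Bonferroni can be switched on.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bouts import Bout, EventSet, detect_arousals, segment_bouts, time_to_resume_sleep
from .errors import ValidationError
from .hypnogram import DARK, LIGHT, NREM, REM, WAKE, Hypnogram

WINDOWS = ("H24", "LIGHT", "DARK")

METRICS = (
    "pct_wake",
    "pct_nrem",
    "pct_rem",
    "n_nrem_bouts",
    "n_rem_bouts",
    "mean_nrem_bout_min",
    "mean_rem_bout_min",
    "arousals_per_h_sleep",
    "mean_resume_latency_min",
)


@dataclass
class SleepSummary:
    """Per-animal metrics, one row per available window."""

    table: pd.DataFrame
    animal: str | None = None

    def value(self, metric: str, window: str = "H24") -> float:
        if window not in self.table.index:
            raise ValidationError(f"window {window!r} absent from this recording")
        return float(self.table.loc[window, metric])


def _window_masks(hyp: Hypnogram) -> dict[str, np.ndarray]:
    masks = {"H24": np.ones(len(hyp), dtype=bool)}
    if hyp.phase is not None:
        for name, code in (("LIGHT", LIGHT), ("DARK", DARK)):
            m = hyp.phase == code
            if m.any():
                masks[name] = m
            else:
                warnings.warn(f"window {name} absent from recording; omitted")
    return masks


def summarize(
    hyp: Hypnogram,
    bouts: list[Bout] | None = None,
    events: EventSet | None = None,
) -> SleepSummary:
    """Compute the full metric table for one animal.

    Bouts and events are derived from the hypnogram when not supplied.
    Percentages come from epoch counts, so the 24-h value of each state is
    the epoch-weighted mean of the light and dark percentages (the exact
    arithmetic mean when the two phases are equal length).  Bouts and
    events are assigned to the phase of their onset epoch.  Metrics with
    no supporting events are NaN.
    """
    if bouts is None:
        bouts = segment_bouts(hyp)
    if events is None:
        events = time_to_resume_sleep(hyp)
    arousals = events.arousals if events.arousals else detect_arousals(hyp)

    rows = {}
    for window, mask in _window_masks(hyp).items():
        stages = hyp.stages[mask]
        row = {
            "pct_wake": 100.0 * np.mean(stages == WAKE),
            "pct_nrem": 100.0 * np.mean(stages == NREM),
            "pct_rem": 100.0 * np.mean(stages == REM),
        }
        for kind, prefix in ((NREM, "nrem"), (REM, "rem")):
            kb = [b for b in bouts if b.kind == kind and mask[b.start_epoch]]
            row[f"n_{prefix}_bouts"] = float(len(kb))
            row[f"mean_{prefix}_bout_min"] = (
                float(np.mean([b.duration_min for b in kb])) if kb else np.nan
            )
        sleep_h = ((stages == NREM) | (stages == REM)).sum() * hyp.epoch_s / 3600.0
        n_arousals = sum(1 for a in arousals if mask[a])
        row["arousals_per_h_sleep"] = n_arousals / sleep_h if sleep_h > 0 else np.nan
        lat = [
            l
            for o, l in zip(events.wake_onsets, events.resume_latencies)
            if mask[o]
        ]
        row["mean_resume_latency_min"] = float(np.mean(lat)) if lat else np.nan
        rows[window] = row
    return SleepSummary(table=pd.DataFrame(rows).T.reindex(columns=list(METRICS)))


@dataclass
class GroupComparison:
    """Unpaired two-tailed Student's t comparison of one metric."""

    metric: str
    window: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: int
    p: float

    def summary(self) -> str:
        return (
            f"{self.metric} [{self.window}]: "
            f"{self.mean_a:.3g} ± {self.sem_a:.2g} (n={self.n_a}) vs "
            f"{self.mean_b:.3g} ± {self.sem_b:.2g} (n={self.n_b}); "
            f"t({self.df}) = {self.t:.3f}, p = {self.p:.4g}"
        )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def compare_groups(
    summaries_a: list[SleepSummary],
    summaries_b: list[SleepSummary],
    metric: str,
    window: str = "H24",
) -> GroupComparison:
    """Pooled-variance Student's t test between two groups of animals.

    Animals for which the metric is undefined (NaN) are excluded with a
    warning; at least two animals per group must remain.
    """
    vals = []
    for summaries in (summaries_a, summaries_b):
        v = np.array([s.value(metric, window) for s in summaries], dtype=float)
        if np.isnan(v).any():
            warnings.warn(f"excluding {int(np.isnan(v).sum())} animal(s) with undefined {metric}")
            v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValidationError(f"fewer than 2 animals with defined {metric}")
        vals.append(v)
    a, b = vals
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * sstats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return GroupComparison(
        metric=metric,
        window=window,
        mean_a=float(a.mean()),
        sem_a=_sem(a),
        n_a=na,
        mean_b=float(b.mean()),
        sem_b=_sem(b),
        n_b=nb,
        t=float(t),
        df=df,
        p=p,
    )


def report(
    summaries_by_group: dict[str, list[SleepSummary]],
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort tables: group means ± SEM per metric and window, plus the
    pairwise comparison table when exactly two groups are present.

    When ``out_dir`` is given, writes ``summary.csv``, ``comparisons.csv``
    and ``animals.json`` (per-animal metric tables, which reproduce the
    summary tables exactly on re-read).
    """
    groups = list(summaries_by_group)
    if not groups or any(len(v) < 1 for v in summaries_by_group.values()):
        raise ValidationError("need at least one animal per group")

    def values(group: str, metric: str, window: str) -> np.ndarray:
        out = []
        for s in summaries_by_group[group]:
            try:
                out.append(s.value(metric, window))
            except ValidationError:  # window absent from this recording
                out.append(np.nan)
        return np.asarray(out, dtype=float)

    rows = []
    for metric in METRICS:
        for window in WINDOWS:
            row: dict[str, object] = {"metric": metric, "window": window}
            for g in groups:
                v = values(g, metric, window)
                v = v[~np.isnan(v)]
                row[f"{g}_mean"] = v.mean() if v.size else np.nan
                row[f"{g}_sem"] = _sem(v)
                row[f"{g}_n"] = v.size
            rows.append(row)
    summary_df = pd.DataFrame(rows)

    comp_rows = []
    for metric in METRICS:
        for window in WINDOWS:
            crow: dict[str, object] = {"metric": metric, "window": window, "t": np.nan, "p": np.nan}
            if len(groups) == 2:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        c = compare_groups(
                            summaries_by_group[groups[0]],
                            summaries_by_group[groups[1]],
                            metric,
                            window,
                        )
                    crow["t"], crow["p"] = c.t, c.p
                except ValidationError:
                    pass
            comp_rows.append(crow)
    comparisons_df = pd.DataFrame(comp_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out / "summary.csv", index=False)
        comparisons_df.to_csv(out / "comparisons.csv", index=False)
        payload = {
            g: [
                {
                    "animal": s.animal or f"{g}{i}",
                    "metrics": {
                        w: {m: s.table.loc[w, m] for m in METRICS}
                        for w in s.table.index
                    },
                }
                for i, s in enumerate(summaries_by_group[g])
            ]
            for g in groups
        }
        (out / "animals.json").write_text(json.dumps(payload, indent=1, default=float))
    return summary_df, comparisons_df
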