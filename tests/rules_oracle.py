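"""Independent brute-force evaluator of the bout/arousal/latency rules.

Deliberately written as literal position-by-position string scans of the
stage sequence, with no shared code or run-length encoding, so it can
serve as an oracle for the production state machine.
"""
from __future__ import annotations

OPEN = {"N": 3, "R": 2, "W": 3}
SLEEP = "NR"


def _terminator_starts_at(s: str, t: int, state: str) -> bool:
    if state == "N":
        return s[t : t + 3] == "WWW" or s[t : t + 2] == "RR"
    # REM and WAKE bouts: three consecutive epochs of any other state
    seg = s[t : t + 3]
    return len(seg) == 3 and all(c != state for c in seg)


def brute_bouts(s: str) -> list[tuple[str, int, int]]:
    """All bouts as (kind, start, end) via a literal left-to-right scan."""
    bouts = []
    i, n = 0, len(s)
    while i < n:
        opened = None
        for j in range(i, n):
            st = s[j]
            if s[j : j + OPEN[st]] == st * OPEN[st]:
                opened = (j, st)
                break
        if opened is None:
            break
        j, st = opened
        end = None
        for t in range(j + 1, n):
            if _terminator_starts_at(s, t, st):
                end = t
                break
        if end is None:
            last = max(q for q in range(j, n) if s[q] == st)
            end = last + 1
        bouts.append((st, j, end))
        i = end
    return bouts


def brute_arousals(s: str) -> list[int]:
    """Wake-run onsets preceded by three consecutive sleep epochs."""
    out = []
    for t in range(1, len(s)):
        if s[t] == "W" and s[t - 1] != "W":
            if t >= 3 and all(c in SLEEP for c in s[t - 3 : t]):
                out.append(t)
    return out


def brute_resume_latencies(s: str, epoch_s: float = 10.0) -> list[tuple[int, float]]:
    """(wake onset, latency in minutes) for wake runs of >= 3 epochs."""
    events = []
    for t in range(len(s)):
        if s[t] == "W" and (t == 0 or s[t - 1] != "W") and s[t : t + 3] == "WWW":
            for u in range(t + 1, len(s) - 2):
                if all(c in SLEEP for c in s[u : u + 3]):
                    events.append((t, (u - t) * epoch_s / 60.0))
                    break
    return events
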