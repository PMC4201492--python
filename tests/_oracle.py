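"""Independent day-by-day interpreter of the disease-state rules.

Used only as a test oracle: it re-derives the course labeling directly
from the clinical rules, one day label at a time, with per-day arrays and
lookahead run lengths instead of the package's interval/state-machine
bookkeeping.  Kept deliberately separate from the implementation under
test.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

THRESH = 14
SPAN = 180


def day_level_course(
    signs: Sequence[bool],
    start_in_episode: bool = False,
) -> Tuple[List[str], List[Tuple[int, int, str]]]:
    """Return (per-day labels, episodes as (onset, duration, kind))."""
    signs = [bool(s) for s in signs]
    n = len(signs)
    # lookahead: length of the maximal run starting at each run boundary
    run_start = [0] * n
    for i in range(1, n):
        run_start[i] = run_start[i - 1] if signs[i] == signs[i - 1] else i
    run_len = {}
    for i in range(n):
        run_len[run_start[i]] = run_len.get(run_start[i], 0) + 1

    labels = [""] * n
    episodes: List[dict] = []
    state = "EP" if start_in_episode else "NULL"
    kind = "DE"
    if start_in_episode:
        episodes.append({"onset": 0, "end": None, "kind": "DE"})
    rest_start = -1
    recovered = False

    i = 0
    while i < n:
        L = run_len[i]
        neg = signs[i]
        if state == "NULL":
            if neg and L >= THRESH:
                state, kind = "EP", "DE"
                episodes.append({"onset": i, "end": None, "kind": "DE"})
                word = "DEPRESSIVE_EPISODE"
            else:
                word = "NULL"
        elif state == "EP":
            if neg:
                word = "DEPRESSIVE_EPISODE" if kind == "DE" else "RELAPSE"
            elif L < THRESH:
                word = "REBOUND_DE" if kind == "DE" else "REBOUND_RELAPSE"
            else:
                episodes[-1]["end"] = i
                state, rest_start, recovered = "REST", i, False
                word = "REMISSION"
        else:  # REST
            if not neg:
                word = "RECOVERY" if recovered else "REMISSION"
            elif L < THRESH:
                word = (
                    "INTERRUPTED_RECOVERY" if recovered else "INTERRUPTED_REMISSION"
                )
            else:
                kind = "DE" if recovered else "RELAPSE"
                state = "EP"
                episodes.append({"onset": i, "end": None, "kind": kind})
                word = "DEPRESSIVE_EPISODE" if kind == "DE" else "RELAPSE"
        for j in range(i, i + L):
            labels[j] = word
        if state == "REST" and not recovered and (i + L - rest_start) >= SPAN:
            recovered = True
            for j in range(rest_start, i + L):
                if labels[j] == "REMISSION":
                    labels[j] = "RECOVERY"
                elif labels[j] == "INTERRUPTED_REMISSION":
                    labels[j] = "INTERRUPTED_RECOVERY"
        i += L

    episode_list = [
        (e["onset"], (e["end"] if e["end"] is not None else n) - e["onset"], e["kind"])
        for e in episodes
    ]
    return labels, episode_list
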