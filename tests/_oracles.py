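"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately take a different computational route from the package:
the sessionizer oracle derives session membership from pairwise interval
logic over activity events (O(n^2)), and the Ward oracle agglomerates by
exhaustive evaluation of every candidate merge's within-SS increase.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np

from portaltypes.logio import LogRecord


def _mins(a: datetime, b: datetime) -> float:
    return (b - a).total_seconds() / 60.0


def oracle_sessionize(records, timeout_mins: float, gap_mins: float):
    """Re-derive merged sessions for one patient's ordered records.

    Returns a list of dicts: {start, end, ended_by, clicks (list of record
    indices into ``records``), n_merged}.
    """
    activity = [
        (i, r) for i, r in enumerate(records) if r.event in ("login", "click")
    ]
    logouts = [(i, r) for i, r in enumerate(records) if r.event == "logout"]
    if not activity:
        return []

    def valid_logout_after(t_last: datetime, before: datetime | None):
        """Earliest logout within the timeout of t_last and (if given) before
        the next activity instant."""
        for _, lo in logouts:
            if lo.timestamp < t_last:
                continue
            if before is not None and lo.timestamp >= before:
                continue
            if _mins(t_last, lo.timestamp) <= timeout_mins:
                return lo.timestamp
        return None

    # group consecutive activity events into raw sessions
    groups: list[list[int]] = [[0]]
    for j in range(1, len(activity)):
        prev_i, prev = activity[j - 1]
        cur_i, cur = activity[j]
        boundary = (
            cur.event == "login"
            or _mins(prev.timestamp, cur.timestamp) > timeout_mins
            or valid_logout_after(prev.timestamp, cur.timestamp) is not None
        )
        groups.append([j]) if boundary else groups[-1].append(j)

    raw = []
    for g in groups:
        first_i, first = activity[g[0]]
        last_i, last = activity[g[-1]]
        nxt = activity[g[-1] + 1][1].timestamp if g[-1] + 1 < len(activity) else None
        logout_t = valid_logout_after(last.timestamp, nxt)
        if logout_t is not None:
            end, ended_by = logout_t, "logout"
        else:
            end, ended_by = last.timestamp, "timeout"
        raw.append(
            {
                "start": first.timestamp,
                "end": end,
                "ended_by": ended_by,
                "clicks": [activity[j][0] for j in g if activity[j][1].event == "click"],
                "n_merged": 1,
            }
        )

    # transitive merge of sessions <= gap_mins apart
    merged = []
    for s in raw:
        if merged and _mins(merged[-1]["end"], s["start"]) <= gap_mins:
            prev = merged[-1]
            prev["end"] = s["end"]
            prev["ended_by"] = s["ended_by"]
            prev["clicks"] = prev["clicks"] + s["clicks"]
            prev["n_merged"] += s["n_merged"]
        else:
            merged.append(dict(s))
    return merged


def random_stream(rng: np.random.Generator, max_events: int = 20,
                  pid: str = "p1") -> list[LogRecord]:
    """A random single-patient event stream exercising every session rule:
    orphan clicks, stray logouts, gaps straddling the timeout, and
    re-logins inside the merge window."""
    from portaltypes.logio import FUNCTION_CODES

    n = int(rng.integers(1, max_events + 1))
    t = datetime(2006, 3, 1, 8, 0)
    out = []
    for _ in range(n):
        kind = rng.choice(["login", "click", "logout"], p=[0.2, 0.6, 0.2])
        fn = FUNCTION_CODES[rng.integers(len(FUNCTION_CODES))] if kind == "click" else None
        out.append(LogRecord(pid, t, kind, fn))
        # gaps concentrated near the 3-min merge and 20-min timeout boundaries
        gap = float(rng.choice([0.5, 1.0, 2.9, 3.0, 3.1, 10.0, 19.9, 20.0, 20.1, 45.0]))
        t = t + timedelta(minutes=gap)
    return out


def oracle_ward_merges(X: np.ndarray):
    """Exhaustive minimum-variance agglomeration.

    At each step evaluates every candidate pair's increase in total
    within-cluster SS and merges the minimum (ties: lowest pair index).
    Returns [(leafset_a, leafset_b, d_sse), ...].
    """
    X = np.asarray(X, dtype=float)

    def sse(idx):
        sub = X[sorted(idx)]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sse(clusters[i] | clusters[j]) - sse(clusters[i]) - sse(clusters[j])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def oracle_adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """ARI by explicit O(n^2) pair enumeration."""
    n = len(a)
    same_a = same_b = same_both = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            same_a += sa
            same_b += sb
            same_both += sa and sb
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2.0
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)
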