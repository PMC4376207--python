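"""Reconstruct portal sessions from ordered event records.

A session opens at a login (or at an orphan click with no open session —
real logs lose logins, and dropping clicks would break click conservation)
and closes at an explicit logout or after more than ``timeout_mins`` of
inactivity.  Timed-out sessions end at the last observed activity: the idle
tail is excluded from the session length.  Sessions separated by at most
``gap_mins`` are treated as one instance of portal activity and merged,
with the inter-session gap counted in the merged length.

Patients with at most one post-merge session in the study window are
classified as non-users and excluded from all downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import pandas as pd

from portaltypes.logio import LogRecord

__all__ = [
    "Session",
    "PatientSessions",
    "build_raw_sessions",
    "merge_adjacent",
    "page_view_lengths",
    "sessionize_cohort",
    "sessions_frame",
    "DEFAULT_TIMEOUT_MINS",
    "DEFAULT_MERGE_GAP_MINS",
]

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT_MINS = 20.0
DEFAULT_MERGE_GAP_MINS = 3.0


@dataclass
class Session:
    """One merged, timeout-adjusted interval of contiguous portal activity."""

    patient_id: str
    start: datetime
    end: datetime
    ended_by: str  # "logout" | "timeout"
    clicks: list[tuple[datetime, str]] = field(default_factory=list)
    n_merged: int = 1

    @property
    def length_mins(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    @property
    def n_clicks(self) -> int:
        return len(self.clicks)


@dataclass
class PatientSessions:
    patient_id: str
    sessions: list[Session]
    user_class: str  # "active" | "non_user"

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def _mins(a: datetime, b: datetime) -> float:
    return (b - a).total_seconds() / 60.0


def build_raw_sessions(
    records: Sequence[LogRecord],
    timeout_mins: float = DEFAULT_TIMEOUT_MINS,
) -> list[Session]:
    """Split one patient's time-ordered records into raw (unmerged) sessions.

    Rules, applied in a single forward pass:

    * ``login`` always opens a new session, closing any open one at its last
      activity (``ended_by="timeout"`` — no logout was observed for it).
    * ``click`` extends the open session if the gap since the last activity
      is ``<= timeout_mins``; a strictly larger gap closes the old session at
      its last activity and the click opens a new (implicit) session.
    * ``logout`` within the timeout closes the session at the logout instant;
      a logout with no open session (or one already timed out) is ignored
      with a warning.

    Degenerate inputs never raise; an empty record list yields no sessions.
    """
    if timeout_mins <= 0:
        raise ValueError("timeout_mins must be positive")
    sessions: list[Session] = []
    cur: Session | None = None
    last_activity: datetime | None = None

    def close(ended_by: str, end: datetime) -> None:
        nonlocal cur
        assert cur is not None
        cur.end = end
        cur.ended_by = ended_by
        sessions.append(cur)
        cur = None

    for rec in records:
        if cur is not None and _mins(last_activity, rec.timestamp) > timeout_mins:
            close("timeout", last_activity)
        if rec.event == "login":
            if cur is not None:
                close("timeout", last_activity)
            cur = Session(rec.patient_id, rec.timestamp, rec.timestamp, "timeout")
            last_activity = rec.timestamp
        elif rec.event == "click":
            if cur is None:
                cur = Session(rec.patient_id, rec.timestamp, rec.timestamp, "timeout")
            cur.clicks.append((rec.timestamp, rec.function))
            last_activity = rec.timestamp
        elif rec.event == "logout":
            if cur is None:
                logger.warning(
                    "patient %s: logout at %s with no open session; ignored",
                    rec.patient_id,
                    rec.timestamp,
                )
                continue
            close("logout", rec.timestamp)
            last_activity = rec.timestamp
    if cur is not None:
        close("timeout", last_activity)
    return sessions


def merge_adjacent(
    sessions: Sequence[Session],
    gap_mins: float = DEFAULT_MERGE_GAP_MINS,
) -> list[Session]:
    """Combine consecutive sessions at most ``gap_mins`` apart (transitively).

    The merged session spans first start to last end, concatenates clicks,
    sums ``n_merged`` and keeps the last constituent's ``ended_by``.  The gap
    time is counted in the merged length: the merged pair is one instance of
    portal activity.  Overlapping input sessions violate the contract.
    """
    merged: list[Session] = []
    for s in sessions:
        if merged:
            prev = merged[-1]
            gap = _mins(prev.end, s.start)
            if gap < 0:
                raise ValueError(
                    f"overlapping sessions for patient {s.patient_id}: "
                    f"{prev.end} > {s.start}"
                )
            if gap <= gap_mins:
                prev.end = s.end
                prev.ended_by = s.ended_by
                prev.clicks = prev.clicks + list(s.clicks)
                prev.n_merged += s.n_merged
                continue
        merged.append(
            Session(s.patient_id, s.start, s.end, s.ended_by, list(s.clicks), s.n_merged)
        )
    return merged


def page_view_lengths(session: Session) -> list[float]:
    """Minutes from each function click to the next click or to logout.

    The final click's view is measured to the session end only when the
    session ended by an explicit logout; after a timeout there is no observed
    endpoint and the final view is omitted.
    """
    out: list[float] = []
    clicks = session.clicks
    for i in range(len(clicks) - 1):
        out.append(_mins(clicks[i][0], clicks[i + 1][0]))
    if clicks and session.ended_by == "logout":
        out.append(_mins(clicks[-1][0], session.end))
    return out


def sessionize_cohort(
    records: Iterable[LogRecord],
    window: tuple[datetime, datetime],
    timeout_mins: float = DEFAULT_TIMEOUT_MINS,
    gap_mins: float = DEFAULT_MERGE_GAP_MINS,
) -> dict[str, PatientSessions]:
    """Per patient: filter to the half-open window [start, end), build raw
    sessions, merge, and classify active (>= 2 merged sessions) vs non-user.

    Patients with records in the window but <= 1 post-merge session are kept
    in the mapping with ``user_class="non_user"``; the post-merge session
    count is the session count used everywhere downstream.
    """
    w_start, w_end = window
    if w_end <= w_start:
        raise ValueError("window end must be after window start")
    by_patient: dict[str, list[LogRecord]] = {}
    for rec in records:
        if w_start <= rec.timestamp < w_end:
            by_patient.setdefault(rec.patient_id, []).append(rec)
    out: dict[str, PatientSessions] = {}
    for pid, recs in by_patient.items():
        sessions = merge_adjacent(build_raw_sessions(recs, timeout_mins), gap_mins)
        user_class = "active" if len(sessions) >= 2 else "non_user"
        out[pid] = PatientSessions(pid, sessions, user_class)
    return out


def sessions_frame(cohort: Mapping[str, PatientSessions]) -> pd.DataFrame:
    """Audit table of all sessions (one row per merged session)."""
    rows = []
    for pid in sorted(cohort):
        for i, s in enumerate(cohort[pid].sessions, start=1):
            rows.append(
                {
                    "patient_id": pid,
                    "session_index": i,
                    "start": s.start,
                    "end": s.end,
                    "ended_by": s.ended_by,
                    "n_clicks": s.n_clicks,
                    "length_mins": s.length_mins,
                    "n_merged": s.n_merged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "session_index",
            "start",
            "end",
            "ended_by",
            "n_clicks",
            "length_mins",
            "n_merged",
        ],
    )
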