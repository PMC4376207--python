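"""Per-patient usage variables and the cohort feature matrix.

Each active patient is summarised over the 12-month window by 41 variables:

* frequency — ``sess`` (session count), ``hitdays`` (distinct calendar days
  with >= 1 session);
* consistency — ``hitmo`` (distinct calendar months with >= 1 session, max 12);
* duration — ``avg_sess_len_mins``, ``tot_len_mins``;
* intensity — ``avg_view_mins`` (mean page-view length), ``totfxn`` (total
  function clicks), ``avgfxnses`` (clicks per session);
* administrative mix — ``adminfxn``, ``carefxn``, ``ratioac``;
* 30 per-function click counts.

``ratioac`` (administrative-to-care ratio) is > 1.0 when a patient's use is
predominantly administrative.  When ``carefxn`` is zero the denominator is
floored at 1 (so ``ratioac = adminfxn``) and flagged, keeping the matrix
finite.  A session counts toward the hit-day / hit-month of its start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from portaltypes.logio import FUNCTION_CODES
from portaltypes.sessionize import PatientSessions, page_view_lengths

__all__ = [
    "DEFAULT_ADMIN_SET",
    "AdminClassification",
    "UsageProfile",
    "SUMMARY_COLUMNS",
    "MATRIX_COLUMNS",
    "compute_profile",
    "cohort_matrix",
]

#: Appointment-related, directions, provider-detail, proxy, referral and
#: record-keeping functions; everything else is care-related.
DEFAULT_ADMIN_SET: frozenset[str] = frozenset(
    {
        "appt_final",
        "drivingdirections",
        "providerdetails",
        "proxyaccessview",
        "switchcontext",
        "referralreview",
        "referralrequest",
        "addresschangerequest",
        "customerservicerequest",
        "demographics",
        "personlpreferences",
    }
)

SUMMARY_COLUMNS = (
    "sess",
    "hitdays",
    "hitmo",
    "avg_sess_len_mins",
    "tot_len_mins",
    "avg_view_mins",
    "totfxn",
    "avgfxnses",
    "adminfxn",
    "carefxn",
    "ratioac",
)

#: Fixed column order of the cohort matrix: 11 summary + 30 function counts.
MATRIX_COLUMNS: tuple[str, ...] = SUMMARY_COLUMNS + FUNCTION_CODES


@dataclass(frozen=True)
class AdminClassification:
    """Partition of the function vocabulary into administrative vs care."""

    admin_set: frozenset[str] = DEFAULT_ADMIN_SET

    def __post_init__(self) -> None:
        unknown = self.admin_set - set(FUNCTION_CODES)
        if unknown:
            raise ValueError(f"admin_set contains non-vocabulary codes: {sorted(unknown)}")

    @property
    def care_set(self) -> frozenset[str]:
        return frozenset(FUNCTION_CODES) - self.admin_set


@dataclass
class UsageProfile:
    patient_id: str
    sess: int
    hitdays: int
    hitmo: int
    avg_sess_len_mins: float
    tot_len_mins: float
    avg_view_mins: float
    totfxn: int
    avgfxnses: float
    adminfxn: int
    carefxn: int
    ratioac: float
    fn_counts: dict[str, int] = field(default_factory=dict)
    care_zero_flag: bool = False  # ratioac denominator floored at 1
    no_views_flag: bool = False  # no measurable page view; avg_view_mins = 0

    def as_row(self) -> dict[str, float]:
        row = {c: getattr(self, c) for c in SUMMARY_COLUMNS}
        for fn in FUNCTION_CODES:
            row[fn] = self.fn_counts.get(fn, 0)
        return row


def compute_profile(
    patient: PatientSessions,
    classification: AdminClassification | None = None,
) -> UsageProfile:
    """Summarise an active patient's sessions into the 41 usage variables.

    Raises ``ValueError`` for non-active patients: profiles are defined for
    the analytic cohort only.
    """
    if patient.user_class != "active":
        raise ValueError(
            f"patient {patient.patient_id} is {patient.user_class}; "
            "profiles are defined for active users only"
        )
    classification = classification or AdminClassification()
    sessions = patient.sessions
    sess = len(sessions)
    hitdays = len({s.start.date() for s in sessions})
    hitmo = len({(s.start.year, s.start.month) for s in sessions})
    tot_len = sum(s.length_mins for s in sessions)
    views: list[float] = []
    fn_counts = {fn: 0 for fn in FUNCTION_CODES}
    for s in sessions:
        views.extend(page_view_lengths(s))
        for _, fn in s.clicks:
            fn_counts[fn] += 1
    totfxn = sum(fn_counts.values())
    adminfxn = sum(fn_counts[fn] for fn in classification.admin_set)
    carefxn = totfxn - adminfxn
    care_zero = carefxn == 0
    ratioac = adminfxn / max(carefxn, 1)
    no_views = len(views) == 0
    avg_view = sum(views) / len(views) if views else 0.0
    return UsageProfile(
        patient_id=patient.patient_id,
        sess=sess,
        hitdays=hitdays,
        hitmo=hitmo,
        avg_sess_len_mins=tot_len / sess,
        tot_len_mins=tot_len,
        avg_view_mins=avg_view,
        totfxn=totfxn,
        avgfxnses=totfxn / sess,
        adminfxn=adminfxn,
        carefxn=carefxn,
        ratioac=ratioac,
        fn_counts=fn_counts,
        care_zero_flag=care_zero,
        no_views_flag=no_views,
    )


def cohort_matrix(profiles: Iterable[UsageProfile]) -> pd.DataFrame:
    """Assemble profiles into the patients x 41 feature matrix.

    Rows are indexed by patient_id, columns follow :data:`MATRIX_COLUMNS`.
    Functions a patient never clicked are explicit zeros; duplicate patient
    ids are an error.
    """
    rows: dict[str, dict[str, float]] = {}
    for p in profiles:
        if p.patient_id in rows:
            raise ValueError(f"duplicate patient_id {p.patient_id!r}")
        rows[p.patient_id] = p.as_row()
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(MATRIX_COLUMNS))
    matrix.index.name = "patient_id"
    return matrix.sort_index()


def profiles_for_cohort(
    cohort: Mapping[str, PatientSessions],
    classification: AdminClassification | None = None,
) -> list[UsageProfile]:
    """Profiles for every active patient in a sessionized cohort."""
    return [
        compute_profile(ps, classification)
        for pid, ps in sorted(cohort.items())
        if ps.user_class == "active"
    ]
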