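"""Synthetic 12-month portal event logs from behavioural archetypes.

Each archetype is a small generative model of one user type: a probability
that a month contains any activity (consistency), a shifted-Poisson count of
sessions per active month (frequency), a shifted-Poisson count of clicks per
session (intensity), a multinomial over the 30 portal functions (functional
signature), log-normal inter-click gaps (page-view length), and
probabilities of ending a session with an explicit logout and of an
immediate (<= 3 min) re-login that exercises the session-merge rule.

The default eight archetypes mirror the qualitative signatures of the user
types the analysis is meant to recover: a low-intensity dabbler, a rare but
intense visitor, a messenger, an appointment preparer (the only type whose
expected administrative use exceeds its care-related use), a lab tracker,
a biometric monitor, a proxy user, and a record updater.  Cohorts also
include non-users (zero or one session) to exercise the exclusion path.

Inter-click gaps are truncated below the inactivity timeout so a generated
session is never split by the sessionizer; ground-truth labels therefore
stay exact at the session level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from portaltypes.logio import FUNCTION_CODES, LogRecord

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohort",
    "default_archetypes",
    "generate_cohort",
    "planted_expectations",
    "DEFAULT_WINDOW",
]

#: Default 12-month study window (half-open).
DEFAULT_WINDOW = (datetime(2005, 11, 1), datetime(2006, 11, 1))

_RELOGIN_MEAN_CLICKS = 3.0  # 1 + Poisson(2) clicks in a merged continuation


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one synthetic user type."""

    name: str
    monthly_activity_prob: float  # P(month has >= 1 session)
    sessions_per_active_month: float  # mean of 1 + Poisson(mean - 1)
    clicks_per_session: float  # mean of 1 + Poisson(mean - 1)
    function_weights: dict[str, float] = field(default_factory=dict)
    inter_click_mins: tuple[float, float] = (0.6, 0.8)  # lognormal (mean, sigma)
    logout_prob: float = 0.7
    relogin_prob: float = 0.1
    signature: tuple[str, ...] = ()  # functions this type is the heavy user of
    mean_age: float = 59.0
    female_prob: float = 0.43

    def validate(self) -> None:
        for p, nm in [
            (self.monthly_activity_prob, "monthly_activity_prob"),
            (self.logout_prob, "logout_prob"),
            (self.relogin_prob, "relogin_prob"),
            (self.female_prob, "female_prob"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{self.name}: {nm}={p} outside [0, 1]")
        if self.sessions_per_active_month < 1 or self.clicks_per_session < 1:
            raise ValueError(f"{self.name}: count means must be >= 1")
        if set(self.function_weights) - set(FUNCTION_CODES):
            raise ValueError(f"{self.name}: unknown function in weights")
        w = np.array([self.function_weights.get(f, 0.0) for f in FUNCTION_CODES])
        if (w < 0).any() or w.sum() == 0:
            raise ValueError(f"{self.name}: weights must be non-negative, not all zero")
        mean, sigma = self.inter_click_mins
        if mean <= 0 or sigma <= 0:
            raise ValueError(f"{self.name}: inter_click_mins must be positive")


#: Baseline (care-heavy) click mix shared by every archetype; signatures
#: multiply the relevant entries.
_BASE_WEIGHTS: dict[str, float] = {
    "labresults": 3.0,
    "labtests": 4.0,
    "resultcomponentgraphing": 0.4,
    "encounterreview": 1.0,
    "encounterdetails": 0.7,
    "allergies": 0.2,
    "immunizations": 0.2,
    "problemlist": 0.2,
    "messaging": 4.0,
    "flowsheetreportslist": 0.2,
    "flowsheetreportdetails": 0.3,
    "healthmaintenance": 0.3,
    "healthmaintenanceschedule": 0.1,
    "healthsnapshot": 0.2,
    "histories": 0.2,
    "letters": 0.3,
    "medication": 1.5,
    "medicationrenewalrequest": 0.3,
    "patientnotes": 0.1,
    "personlpreferences": 0.1,
    "demographics": 0.1,
    "providerdetails": 0.2,
    "addresschangerequest": 0.03,
    "referralreview": 0.3,
    "referralrequest": 0.1,
    "appt_final": 2.5,
    "proxyaccessview": 0.2,
    "customerservicerequest": 0.1,
    "drivingdirections": 0.05,
    "switchcontext": 0.05,
}


def _boost(factors: dict[str, float]) -> dict[str, float]:
    w = dict(_BASE_WEIGHTS)
    for fn, f in factors.items():
        w[fn] = w[fn] * f
    return w


def default_archetypes() -> list[ArchetypeSpec]:
    """Eight pairwise-separated archetypes.

    Each archetype's signature functions carry at least 3x the weight they
    carry in any other archetype; the appointment-preparer is the only type
    whose expected administrative-to-care ratio exceeds 1; the
    rare-intense type has the lowest monthly activity probability and the
    highest clicks-per-session mean.
    """
    specs = [
        ArchetypeSpec(
            name="casual_dabbler",
            monthly_activity_prob=0.55,
            sessions_per_active_month=2.3,
            clicks_per_session=7.0,
            function_weights=dict(_BASE_WEIGHTS),
            inter_click_mins=(0.6, 0.8),
        ),
        ArchetypeSpec(
            name="rare_intense",
            monthly_activity_prob=0.34,
            sessions_per_active_month=1.9,
            clicks_per_session=18.0,
            function_weights=dict(_BASE_WEIGHTS),
            inter_click_mins=(0.7, 0.8),
        ),
        ArchetypeSpec(
            name="messenger",
            monthly_activity_prob=0.78,
            sessions_per_active_month=4.9,
            clicks_per_session=10.0,
            function_weights=_boost(
                {
                    "messaging": 5.0,
                    "medicationrenewalrequest": 8.0,
                    "referralrequest": 12.0,
                    "customerservicerequest": 12.0,
                    "letters": 6.0,
                }
            ),
            signature=(
                "messaging",
                "medicationrenewalrequest",
                "referralrequest",
                "customerservicerequest",
                "letters",
            ),
        ),
        ArchetypeSpec(
            name="appointment_preparer",
            monthly_activity_prob=0.78,
            sessions_per_active_month=4.9,
            clicks_per_session=8.3,
            function_weights=_boost(
                {
                    "appt_final": 7.0,
                    "providerdetails": 12.0,
                    "drivingdirections": 30.0,
                    "referralreview": 4.0,
                }
            ),
            signature=("appt_final", "providerdetails", "drivingdirections"),
            inter_click_mins=(0.8, 0.8),
        ),
        ArchetypeSpec(
            name="lab_tracker",
            monthly_activity_prob=0.85,
            sessions_per_active_month=5.7,
            clicks_per_session=14.5,
            function_weights=_boost(
                {
                    "labresults": 5.0,
                    "labtests": 5.0,
                    "resultcomponentgraphing": 7.0,
                    "histories": 4.0,
                }
            ),
            signature=("labresults", "labtests", "resultcomponentgraphing"),
        ),
        ArchetypeSpec(
            name="biometric_monitor",
            monthly_activity_prob=0.57,
            sessions_per_active_month=3.05,
            clicks_per_session=14.0,
            function_weights=_boost(
                {"flowsheetreportslist": 18.0, "flowsheetreportdetails": 18.0}
            ),
            signature=("flowsheetreportslist", "flowsheetreportdetails"),
        ),
        ArchetypeSpec(
            name="proxy_user",
            monthly_activity_prob=0.85,
            sessions_per_active_month=5.2,
            clicks_per_session=10.0,
            function_weights=_boost({"proxyaccessview": 40.0, "switchcontext": 30.0}),
            signature=("proxyaccessview", "switchcontext"),
            inter_click_mins=(1.4, 0.8),
            mean_age=39.5,
            female_prob=0.8,
        ),
        ArchetypeSpec(
            name="record_updater",
            monthly_activity_prob=0.63,
            sessions_per_active_month=3.8,
            clicks_per_session=12.6,
            function_weights=_boost(
                {"demographics": 12.0, "addresschangerequest": 40.0,
                 "personlpreferences": 8.0}
            ),
            signature=("demographics", "addresschangerequest", "personlpreferences"),
            inter_click_mins=(0.5, 0.8),
        ),
    ]
    for s in specs:
        s.validate()
    return specs


@dataclass
class SyntheticCohort:
    records: list[LogRecord]
    truth: dict[str, str]  # patient_id -> archetype name ("non_user" for extras)
    demographics: pd.DataFrame


def _shifted_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=size)


def _lognormal_mins(
    rng: np.random.Generator, mean: float, sigma: float, size: int
) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    # truncate below the 20-min inactivity timeout so sessions never split
    return np.minimum(rng.lognormal(mu, sigma, size=size), 19.0)


def _sec(t: datetime) -> datetime:
    """Clamp to whole seconds, the log dialect's resolution."""
    return t.replace(microsecond=0)


def _month_starts(window: tuple[datetime, datetime]) -> list[datetime]:
    months = []
    cur = datetime(window[0].year, window[0].month, 1)
    while cur < window[1]:
        months.append(cur)
        cur = datetime(cur.year + cur.month // 12, cur.month % 12 + 1, 1)
    return months


def _gen_session(
    rng: np.random.Generator,
    spec: ArchetypeSpec,
    pid: str,
    start: datetime,
    fn_probs: np.ndarray,
    mean_clicks: float,
) -> tuple[list[LogRecord], datetime, bool]:
    """One raw session; returns (records, end instant, ended_by_logout)."""
    start = _sec(start)
    recs = [LogRecord(pid, start, "login")]
    n_clicks = int(_shifted_poisson(rng, mean_clicks, 1)[0])
    gaps = _lognormal_mins(rng, *spec.inter_click_mins, size=n_clicks + 1)
    t = start
    for i in range(n_clicks):
        t = _sec(t + timedelta(minutes=float(gaps[i])))
        fn = FUNCTION_CODES[rng.choice(len(FUNCTION_CODES), p=fn_probs)]
        recs.append(LogRecord(pid, t, "click", fn))
    if rng.random() < spec.logout_prob:
        t = _sec(t + timedelta(minutes=float(gaps[-1])))
        recs.append(LogRecord(pid, t, "logout"))
        return recs, t, True
    return recs, t, False


def generate_cohort(
    specs: list[ArchetypeSpec],
    n_per_type: int | list[int],
    window: tuple[datetime, datetime] = DEFAULT_WINDOW,
    seed: int = 0,
    n_nonusers: int = 0,
) -> SyntheticCohort:
    """Sample a full cohort of event logs, truth labels and demographics.

    ``n_per_type`` is a shared count or one count per archetype.  Non-users
    get zero clicks or a single session and exist to exercise the exclusion
    path.  Fully reproducible from ``seed``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    for s in specs:
        s.validate()
    counts = (
        [n_per_type] * len(specs) if isinstance(n_per_type, int) else list(n_per_type)
    )
    if len(counts) != len(specs) or any(c < 0 for c in counts):
        raise ValueError("n_per_type must give a non-negative count per spec")
    rng = np.random.default_rng(seed)
    months = _month_starts(window)
    records: list[LogRecord] = []
    truth: dict[str, str] = {}
    demo_rows = []
    pid_counter = 0
    for spec, n in zip(specs, counts):
        w = np.array([spec.function_weights.get(f, 0.0) for f in FUNCTION_CODES])
        fn_probs = w / w.sum()
        for _ in range(n):
            pid_counter += 1
            pid = f"P{pid_counter:05d}"
            truth[pid] = spec.name
            demo_rows.append(_draw_demographics(rng, pid, spec))
            session_starts: list[datetime] = []
            for mstart in months:
                if rng.random() >= spec.monthly_activity_prob:
                    continue
                n_sess = int(
                    _shifted_poisson(rng, spec.sessions_per_active_month, 1)[0]
                )
                next_m = datetime(
                    mstart.year + mstart.month // 12, mstart.month % 12 + 1, 1
                )
                span = (next_m - mstart).total_seconds() / 60.0 - 120
                session_starts.extend(
                    mstart + timedelta(minutes=float(m))
                    for m in np.sort(rng.uniform(0, span, size=n_sess))
                )
            for start in session_starts:
                recs, end, _ = _gen_session(
                    rng, spec, pid, start, fn_probs, spec.clicks_per_session
                )
                records.extend(recs)
                if rng.random() < spec.relogin_prob:
                    # immediate re-login: merged back into one activity instance
                    restart = end + timedelta(minutes=float(rng.uniform(0.5, 2.9)))
                    recs2, _, _ = _gen_session(
                        rng, spec, pid, restart, fn_probs, _RELOGIN_MEAN_CLICKS
                    )
                    records.extend(recs2)
    base_spec = specs[0]
    for _ in range(n_nonusers):
        pid_counter += 1
        pid = f"P{pid_counter:05d}"
        truth[pid] = "non_user"
        demo_rows.append(_draw_demographics(rng, pid, base_spec))
        start = window[0] + timedelta(
            minutes=float(rng.uniform(0, (window[1] - window[0]).total_seconds() / 60 - 120))
        )
        if rng.random() < 0.3:
            records.append(LogRecord(pid, _sec(start), "login"))  # lone login, no clicks
        else:
            w = np.array([base_spec.function_weights.get(f, 0.0) for f in FUNCTION_CODES])
            recs, _, _ = _gen_session(rng, base_spec, pid, start, w / w.sum(), 4.0)
            records.extend(recs)
    records.sort(key=lambda r: (r.patient_id, r.timestamp))
    demographics = pd.DataFrame(
        demo_rows,
        columns=[
            "patient_id",
            "age_years",
            "sex",
            "diabetes",
            "cardiovascular",
            "heart_failure",
            "bmi",
        ],
    )
    return SyntheticCohort(records, truth, demographics)


def _draw_demographics(rng: np.random.Generator, pid: str, spec: ArchetypeSpec) -> dict:
    return {
        "patient_id": pid,
        "age_years": float(np.round(np.clip(rng.normal(spec.mean_age, 10.0), 18, 95), 1)),
        "sex": "F" if rng.random() < spec.female_prob else "M",
        "diabetes": int(rng.random() < 0.46),
        "cardiovascular": int(rng.random() < 0.28),
        "heart_failure": int(rng.random() < 0.03),
        "bmi": float(np.round(np.clip(rng.normal(31.0, 5.0), 16, 60), 1)),
    }


def planted_expectations(
    spec: ArchetypeSpec,
    window: tuple[datetime, datetime] = DEFAULT_WINDOW,
) -> dict[str, float]:
    """Closed-form expected usage-variable means under the generative model.

    Assumes months, sessions and clicks are independent, and that every
    immediate re-login is merged back (true by construction: restarts occur
    < 3 minutes after the previous end).  Post-merge session counts are
    therefore unaffected by re-logins, while click totals gain the expected
    continuation clicks.
    """
    spec.validate()
    n_months = len(_month_starts(window))
    e_sess = spec.monthly_activity_prob * n_months * spec.sessions_per_active_month
    e_hitmo = spec.monthly_activity_prob * n_months
    clicks_per_merged = spec.clicks_per_session + spec.relogin_prob * _RELOGIN_MEAN_CLICKS
    e_totfxn = e_sess * clicks_per_merged
    w = np.array([spec.function_weights.get(f, 0.0) for f in FUNCTION_CODES])
    probs = w / w.sum()
    fn_means = {fn: e_totfxn * p for fn, p in zip(FUNCTION_CODES, probs)}
    from portaltypes.features import DEFAULT_ADMIN_SET

    e_admin = sum(fn_means[f] for f in DEFAULT_ADMIN_SET)
    e_care = e_totfxn - e_admin
    return {
        "sess": e_sess,
        "hitmo": e_hitmo,
        "totfxn": e_totfxn,
        "avgfxnses": clicks_per_merged,
        "adminfxn": e_admin,
        "carefxn": e_care,
        "ratioac": e_admin / e_care if e_care > 0 else e_admin,
        **fn_means,
    }
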