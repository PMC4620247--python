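"""Cohort selection and incidence-rate reporting.

Implements the surveillance use case's patient-selection rules on canonical
patient records: identify patients whose *first* acute-coronary-syndrome
(ACS) event — acute myocardial infarction or unstable angina — falls in the
accrual window, require at least one year of pre-event history, exclude
deaths within 30 days of the event and patients under 18 at the event.
Survivors get a STARTDATE (ACS + 30 days, allowing the event to stabilize)
and a LASTDATE (minimum of death, transfer-out and the study end).

Reporting: crude incidence rates per 1000 person-years over the populated
data collection set, stratified on exact column values, plus simple column
proportions used for validity checks against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .errors import DataQualityError
from .model import PatientRecord
from .terminology import TerminologyServer

DAYS_PER_YEAR = 365  # fixed-length year: determinism over calendar arithmetic

#: research-side ACS definition: acute MI + unstable angina (MedDRA PTs)
DEFAULT_ACS_CODES = (("MedDRA", "10000891"), ("MedDRA", "10002388"))


@dataclass(frozen=True)
class EligibilityCriteria:
    acs_codes: tuple[tuple[str, str], ...] = DEFAULT_ACS_CODES
    accrual_start: date = date(2005, 1, 1)
    accrual_end: date = date(2011, 12, 31)
    min_history_days: int = 365
    death_exclusion_days: int = 30
    min_age_years: int = 18
    study_end: date = date(2011, 12, 31)
    #: an ACS before the accrual window disqualifies (the in-window event is
    #: then not a *first* event); set False to merely shift the index event
    prior_acs_disqualifies: bool = True

    def __post_init__(self) -> None:
        if self.accrual_start > self.accrual_end:
            raise ValueError("accrual window start after end")
        for name in ("min_history_days", "death_exclusion_days", "min_age_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_criteria(source) -> EligibilityCriteria:
    """Build criteria from a YAML/JSON file or parsed dict; unspecified
    fields keep the use-case defaults."""
    import yaml

    if isinstance(source, dict):
        raw = source
    else:
        from pathlib import Path

        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    kwargs = {}
    if "acs_codes" in raw:
        kwargs["acs_codes"] = tuple(
            (str(s), str(c)) for s, c in raw["acs_codes"]
        )
    for key in ("accrual_start", "accrual_end", "study_end"):
        if key in raw:
            v = raw[key]
            kwargs[key] = v if isinstance(v, date) else date.fromisoformat(str(v))
    for key in (
        "min_history_days",
        "death_exclusion_days",
        "min_age_years",
        "prior_acs_disqualifies",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return EligibilityCriteria(**kwargs)


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    acs_date: date
    start_date: date
    last_date: date
    age_at_acs: int


@dataclass
class EligibilityResult:
    members: list[CohortMember]
    #: exclusion counts keyed by the FIRST failing filter, in rule order
    exclusions: dict[str, int] = field(default_factory=dict)


FILTER_ORDER = (
    "no_first_acs_in_window",
    "insufficient_history",
    "death_within_30d",
    "age_under_18",
    "no_followup_time",
)


def _age_in_years(birth: date, at: date) -> int:
    """Completed years at ``at`` (standard epidemiological convention)."""
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years


def first_acs_event(
    patient: PatientRecord,
    criteria: EligibilityCriteria,
    terminology: TerminologyServer,
) -> date | None:
    """Date of the patient's first ACS event if it lies in the accrual
    window; None otherwise.

    Condition entries are warehouse-coded; matching against the research
    code set goes through the terminology server.  When the earliest ACS
    predates the window it is not a *first* in-window event: by default the
    patient is disqualified entirely."""
    acs_dates = sorted(
        c.start_date
        for c in patient.conditions
        if any(
            terminology.codes_match(code, system, c.code, c.code_system)
            for system, code in criteria.acs_codes
        )
    )
    if not acs_dates:
        return None
    first = acs_dates[0]
    if first < criteria.accrual_start:
        if criteria.prior_acs_disqualifies:
            return None
        in_window = [
            d
            for d in acs_dates
            if criteria.accrual_start <= d <= criteria.accrual_end
        ]
        return in_window[0] if in_window else None
    if first > criteria.accrual_end:
        return None
    return first


def derive_follow_up(
    patient: PatientRecord, acs: date, criteria: EligibilityCriteria
) -> tuple[date, date]:
    """STARTDATE (ACS + 30 days) and LASTDATE (min of death, transfer-out,
    study end)."""
    start = acs + timedelta(days=criteria.death_exclusion_days)
    candidates = [criteria.study_end]
    if patient.death_date is not None:
        candidates.append(patient.death_date)
    if patient.transfer_out_date is not None:
        candidates.append(patient.transfer_out_date)
    return start, min(candidates)


def apply_eligibility(
    patients: list[PatientRecord],
    criteria: EligibilityCriteria,
    terminology: TerminologyServer,
) -> EligibilityResult:
    """Apply the selection rules in their stated order; each excluded
    patient is attributed to the first failing filter."""
    result = EligibilityResult(
        members=[], exclusions={name: 0 for name in FILTER_ORDER}
    )
    for patient in patients:
        acs = first_acs_event(patient, criteria, terminology)
        if acs is None:
            result.exclusions["no_first_acs_in_window"] += 1
            continue
        if patient.registration_date > acs - timedelta(
            days=criteria.min_history_days
        ):
            result.exclusions["insufficient_history"] += 1
            continue
        if patient.death_date is not None and patient.death_date <= acs + timedelta(
            days=criteria.death_exclusion_days
        ):
            result.exclusions["death_within_30d"] += 1
            continue
        age = _age_in_years(patient.birth_date, acs)
        if age < criteria.min_age_years:
            result.exclusions["age_under_18"] += 1
            continue
        start, last = derive_follow_up(patient, acs, criteria)
        if last < start:
            # transferred out (or record ended) during the stabilization
            # window: no follow-up time to contribute
            result.exclusions["no_followup_time"] += 1
            continue
        result.members.append(
            CohortMember(
                patient_id=patient.patient_id,
                acs_date=acs,
                start_date=start,
                last_date=last,
                age_at_acs=age,
            )
        )
    return result


# ---------------------------------------------------------------------------
# reporting on the populated data collection set
# ---------------------------------------------------------------------------


def incidence_rate(
    dcs: pd.DataFrame,
    event_column: str,
    strata: list[str] | None = None,
    start_column: str = "STARTDATE",
    last_column: str = "LASTDATE",
) -> pd.DataFrame:
    """Crude incidence per 1000 person-years, optionally stratified.

    Per patient the person-time at risk runs from STARTDATE to the event or
    LASTDATE, whichever is earlier; events count when the event date falls
    in ``(STARTDATE, LASTDATE]``.  Patients whose event date is on or before
    STARTDATE are prevalent cases and are excluded from the risk set.
    Strata are exact values of the given columns (one ``(all)`` stratum when
    none are given)."""
    strata = strata or []
    rows = []
    for patient_id, row in dcs.iterrows():
        start, last, event = (
            row[start_column],
            row[last_column],
            row[event_column],
        )
        if start is None or last is None:
            continue
        if event is not None and event <= start:
            # prevalent case: outcome on record before follow-up starts;
            # contributes neither an event nor person-time at risk
            continue
        end = last if event is None else min(event, last)
        person_days = (end - start).days
        if person_days < 0:
            raise DataQualityError(
                f"patient {patient_id!r}: negative person-time "
                f"({start} .. {end})"
            )
        is_event = event is not None and start < event <= last
        key = tuple(row[s] for s in strata) if strata else ("(all)",)
        rows.append((key, int(is_event), person_days / DAYS_PER_YEAR))
    frame = pd.DataFrame(rows, columns=["stratum", "events", "person_years"])
    if frame.empty:
        return pd.DataFrame(
            columns=list(strata or ["stratum"])
            + ["events", "person_years", "rate_per_1000py"]
        )
    grouped = (
        frame.groupby("stratum", sort=True)[["events", "person_years"]]
        .sum()
        .reset_index()
    )
    grouped["rate_per_1000py"] = grouped.apply(
        lambda r: 1000.0 * r["events"] / r["person_years"]
        if r["person_years"] > 0
        else float("nan"),
        axis=1,
    )
    names = strata or ["stratum"]
    keys = pd.DataFrame(grouped["stratum"].tolist(), columns=names)
    return pd.concat(
        [keys, grouped[["events", "person_years", "rate_per_1000py"]]],
        axis=1,
    )


def proportion(
    dcs: pd.DataFrame,
    column: str,
    value: str,
    terminology: TerminologyServer | None = None,
    system: str | None = None,
) -> float | None:
    """Share of non-null cells in ``column`` equal to ``value`` (via the
    terminology server's code matching when a system is given).  None when
    the column holds no data."""
    cells = [v for v in dcs[column] if v is not None]
    if not cells:
        return None
    if terminology is not None and system is not None:
        hits = sum(
            terminology.codes_match(value, system, str(v), system)
            for v in cells
        )
    else:
        hits = sum(str(v) == value for v in cells)
    return hits / len(cells)
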