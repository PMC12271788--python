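"""Cohort construction: index dates, exclusions, subcohorts, baseline
covariates, time-to-event tables, and person-year incidence.

The cohort entry date ("index date") is the earliest MASH-positive note date
plus a 90-day offset that absorbs delayed recording in clinical notes.
Patients are excluded — each with exactly one recorded reason — when death or
liver transplant precedes the index date, when the diagnosis itself
post-dates a liver transplant, when age or sex is missing, or when the
patient is under 18 at index.  Included patients split into cirrhosis /
no-cirrhosis subcohorts by baseline ICD coding (codes dated on the index
date count as baseline).

Outcomes follow the epidemiological convention of one row per patient per
outcome: event, administratively censored at the follow-up end, or censored
at a competing event.  Death always competes with non-fatal outcomes.  A
configurable guard window (default 90 days) lets an outcome recorded shortly
*after* a competing event still count as an event, absorbing the same
delayed-recording artefact the index offset does; with ``guard_days=0`` the
builder censors strictly at the first competing event.

Person-years use 365.25 days/year; incidence is reported per 100 PY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

from .registry import CodeList, PatientRecord

ALL_CAUSE_MORTALITY = "all_cause_mortality"
INCIDENT_CIRRHOSIS = "incident_cirrhosis"
LIVER_TRANSPLANT = "liver_transplant"
OUTCOMES = (ALL_CAUSE_MORTALITY, INCIDENT_CIRRHOSIS, LIVER_TRANSPLANT)

CIRRHOSIS = "cirrhosis"
NO_CIRRHOSIS = "no_cirrhosis"

EVENT = "event"
CENSORED_ADMIN = "censored_admin"
CENSORED_COMPETING = "censored_competing"

DAYS_PER_YEAR = 365.25

#: Exclusion reasons, in the priority order they are checked.
EXCLUSION_REASONS = (
    "death_before_index",
    "mash_after_transplant",
    "transplant_before_index",
    "missing_age_or_sex",
    "age_under_18",
)


@dataclass(frozen=True)
class CohortEntry:
    """An evaluated cohort candidate; included iff exclusion_reason is None."""

    patient_id: str
    index_note_date: date
    index_date: date
    exclusion_reason: str | None = None
    subcohort: str | None = None
    decompensated: bool | None = None
    sex: str | None = None
    age_at_index: int | None = None
    bmi_category: str | None = None
    meld3_score: float | None = None

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


@dataclass(frozen=True)
class TimeToEventRow:
    patient_id: str
    outcome: str
    time_days: int
    status: str  # event | censored_admin | censored_competing


def derive_index_date(index_note_date: date, offset_days: int = 90) -> date:
    """Index date = earliest positive note date + offset (default 90 days)."""
    if offset_days < 0:
        raise ValueError("offset_days must be >= 0")
    return index_note_date + timedelta(days=offset_days)


def age_at(record: PatientRecord, on: date) -> int | None:
    """Whole-year age at a date; falls back to age_at_first_note unadjusted."""
    if record.birth_date is not None:
        b = record.birth_date
        return on.year - b.year - ((on.month, on.day) < (b.month, b.day))
    if record.age_at_first_note is not None:
        return int(record.age_at_first_note)
    return None


def apply_exclusions(
    candidates: Mapping[str, date],
    records: Mapping[str, PatientRecord],
    offset_days: int = 90,
    min_age: int = 18,
) -> list[CohortEntry]:
    """Evaluate inclusion for every NLP-flagged candidate.

    ``candidates`` maps patient_id -> earliest positive note date.  Every
    candidate appears exactly once in the output; excluded entries carry the
    first matching reason from :data:`EXCLUSION_REASONS`.  A diagnosis made
    after a liver transplant is recorded under its own reason
    (``mash_after_transplant``) even though it also implies a pre-index
    transplant.
    """
    entries: list[CohortEntry] = []
    for pid in candidates:
        note_date = candidates[pid]
        index_date = derive_index_date(note_date, offset_days)
        rec = records.get(pid)
        entry = CohortEntry(pid, note_date, index_date)

        reason = None
        if rec is None:
            reason = "missing_age_or_sex"
        else:
            age = age_at(rec, index_date)
            if rec.death_date is not None and rec.death_date < index_date:
                reason = "death_before_index"
            elif any(t < note_date for t in rec.transplant_dates):
                reason = "mash_after_transplant"
            elif any(t < index_date for t in rec.transplant_dates):
                reason = "transplant_before_index"
            elif rec.sex is None or age is None:
                reason = "missing_age_or_sex"
            elif age < min_age:
                reason = "age_under_18"

        if reason is not None:
            entries.append(replace(entry, exclusion_reason=reason))
            continue

        labs = {
            name: rec.latest_lab(name, index_date)
            for name in ("bilirubin", "sodium", "inr", "creatinine", "albumin")
        }
        score = (
            None
            if any(v is None for v in labs.values())
            else meld3(rec.sex, labs["bilirubin"], labs["sodium"], labs["inr"],
                       labs["creatinine"], labs["albumin"])
        )
        entries.append(
            replace(
                entry,
                sex=rec.sex,
                age_at_index=age_at(rec, index_date),
                bmi_category=bmi_category(rec.bmi, rec.asian_flag),
                meld3_score=score,
            )
        )
    return entries


def assign_subcohort(
    entry: CohortEntry,
    record: PatientRecord,
    cirrhosis_codes: CodeList,
    decompensation_codes: CodeList | None = None,
) -> CohortEntry:
    """Assign the baseline cirrhosis subcohort (codes dated <= index count)."""
    has_cirr = record.first_code_date(cirrhosis_codes, on_or_before=entry.index_date)
    decomp = None
    if decompensation_codes is not None:
        decomp = (
            record.first_code_date(decompensation_codes, on_or_before=entry.index_date)
            is not None
        )
    return replace(
        entry,
        subcohort=CIRRHOSIS if has_cirr is not None else NO_CIRRHOSIS,
        decompensated=decomp,
    )


def bmi_category(bmi: float | None, asian_flag: bool = False) -> str:
    """WHO BMI category with Asian-specific cut-points.

    Asian: underweight <18.5, normal 18.5-22.9, overweight 23-27.4,
    obese >=27.5.  Non-Asian: 18.5 / 25 / 30.
    """
    if bmi is None:
        return "missing"
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    over, obese = (23.0, 27.5) if asian_flag else (25.0, 30.0)
    if bmi < 18.5:
        return "underweight"
    if bmi < over:
        return "normal"
    if bmi < obese:
        return "overweight"
    return "obese"


def meld3(
    sex: str,
    bilirubin: float,
    sodium: float,
    inr: float,
    creatinine: float,
    albumin: float,
    ndigits: int | None = 2,
) -> float | None:
    """MELD 3.0 liver-disease severity score.

    Inputs: total bilirubin mg/dL, sodium mEq/L, INR, creatinine mg/dL,
    albumin g/dL.  Published clamps apply: bilirubin/INR/creatinine floored
    at 1.0, creatinine capped at 3.0, sodium clamped to [125, 137], albumin
    to [1.5, 3.5].  Returns None when any input is missing (imputation is
    out of scope here).
    """
    inputs = (bilirubin, sodium, inr, creatinine, albumin)
    if any(v is None for v in inputs):
        return None
    if any(v <= 0 for v in inputs):
        raise ValueError("MELD 3.0 inputs must be positive")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    bili = max(bilirubin, 1.0)
    na = min(max(sodium, 125.0), 137.0)
    inr_c = max(inr, 1.0)
    cr = min(max(creatinine, 1.0), 3.0)
    alb = min(max(albumin, 1.5), 3.5)

    score = (
        1.33 * (sex == "female")
        + 4.56 * math.log(bili)
        + 0.82 * (137.0 - na)
        - 0.24 * (137.0 - na) * math.log(bili)
        + 9.09 * math.log(inr_c)
        + 11.14 * math.log(cr)
        + 1.85 * (3.5 - alb)
        - 1.83 * (3.5 - alb) * math.log(cr)
        + 6.43
    )
    return round(score, ndigits) if ndigits is not None else score


_DEFAULT_COMPETING = {
    ALL_CAUSE_MORTALITY: (),
    INCIDENT_CIRRHOSIS: (ALL_CAUSE_MORTALITY, LIVER_TRANSPLANT),
    LIVER_TRANSPLANT: (ALL_CAUSE_MORTALITY,),
}

_OUTCOME_SUBCOHORT = {
    ALL_CAUSE_MORTALITY: None,  # full cohort
    INCIDENT_CIRRHOSIS: NO_CIRRHOSIS,
    LIVER_TRANSPLANT: CIRRHOSIS,
}


def _event_date(
    outcome: str,
    record: PatientRecord,
    index_date: date,
    cirrhosis_codes: CodeList | None,
) -> date | None:
    if outcome == ALL_CAUSE_MORTALITY:
        return record.death_date
    if outcome == LIVER_TRANSPLANT:
        post = [t for t in record.transplant_dates if t > index_date]
        return min(post) if post else None
    if outcome == INCIDENT_CIRRHOSIS:
        if cirrhosis_codes is None:
            raise ValueError("cirrhosis_codes required for the incident_cirrhosis outcome")
        return record.first_code_date(cirrhosis_codes, after=index_date)
    raise ValueError(f"unknown outcome {outcome!r}")


def build_tte(
    entries: Sequence[CohortEntry],
    records: Mapping[str, PatientRecord],
    outcome: str,
    follow_up_end: date,
    competing: Sequence[str] | None = None,
    cirrhosis_codes: CodeList | None = None,
    guard_days: int = 90,
) -> list[TimeToEventRow]:
    """Build the per-patient time-to-event table for one outcome.

    Mortality runs on the full included cohort; incident cirrhosis on the
    no-cirrhosis subcohort; transplant on the cirrhosis subcohort (a
    mismatched entry raises).  Patients whose outcome is already recorded on
    or before the index date are dropped from the risk set.  Otherwise each
    patient yields one row: an event if the outcome occurs by
    ``follow_up_end`` and no competing event precedes it by more than
    ``guard_days``; censoring at the earliest competing event; or
    administrative censoring at ``follow_up_end``.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if competing is None:
        competing = _DEFAULT_COMPETING[outcome]
    need = _OUTCOME_SUBCOHORT[outcome]

    rows: list[TimeToEventRow] = []
    for entry in entries:
        if not entry.included:
            continue
        if need is not None and entry.subcohort != need:
            raise ValueError(
                f"outcome {outcome} requires the {need} subcohort but "
                f"patient {entry.patient_id} is in {entry.subcohort!r}"
            )
        rec = records[entry.patient_id]
        idx = entry.index_date
        o = _event_date(outcome, rec, idx, cirrhosis_codes)
        if o is not None and o <= idx:
            continue  # outcome pre-dates index: not at risk

        comp_dates = [
            c
            for co in competing
            if (c := _event_date(co, rec, idx, cirrhosis_codes)) is not None
            and idx < c <= follow_up_end
        ]
        c = min(comp_dates) if comp_dates else None

        if o is not None and o <= follow_up_end and not (
            c is not None and c < o and (o - c).days > guard_days
        ):
            when, status = o, EVENT
        elif c is not None:
            when, status = c, CENSORED_COMPETING
        else:
            when, status = follow_up_end, CENSORED_ADMIN
        rows.append(
            TimeToEventRow(entry.patient_id, outcome, (when - idx).days, status)
        )
    return rows


def person_years(rows: Iterable[TimeToEventRow]) -> float:
    return sum(r.time_days for r in rows) / DAYS_PER_YEAR


def incidence_rate(n_events: int, py: float) -> float:
    """Events per 100 person-years."""
    if py <= 0:
        raise ValueError("person_years must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return 100.0 * n_events / py


def summarize_tte(rows: Sequence[TimeToEventRow]) -> dict:
    """Events, person-years and incidence per 100 PY for one TTE table."""
    n_events = sum(1 for r in rows if r.status == EVENT)
    py = person_years(rows)
    return {
        "n_at_risk": len(rows),
        "n_events": n_events,
        "person_years": round(py, 1),
        "rate_per_100py": round(incidence_rate(n_events, py), 2) if py > 0 else None,
    }
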