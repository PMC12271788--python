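"""Structured patient registry: demographics, coded events, procedures, labs.

The registry is the flat-file stand-in for an EHR extract: four delimited
tables (patients, coded_events, procedures, labs) with ISO-8601 dates.
Diagnosis code lists support trailing-``*`` prefix wildcards (``K74.6*``)
and are matched case-insensitively with dots retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

TRANSPLANT_CPT = "47135"


@dataclass(frozen=True)
class CodedEvent:
    code_system: str
    code: str
    date: date


@dataclass(frozen=True)
class LabResult:
    name: str
    value: float
    date: date


@dataclass
class PatientRecord:
    """A patient's structured timeline."""

    patient_id: str
    sex: str | None = None  # "female" | "male" | None (missing)
    birth_date: date | None = None
    age_at_first_note: float | None = None
    death_date: date | None = None
    transplant_dates: list[date] = field(default_factory=list)
    coded_events: list[CodedEvent] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    asian_flag: bool = False
    bmi: float | None = None

    def __post_init__(self):
        self.transplant_dates = sorted(self.transplant_dates)

    def first_code_date(self, codes: "CodeList", after: date | None = None,
                        on_or_before: date | None = None) -> date | None:
        """Earliest coded-event date matching ``codes`` within the window
        (strictly after ``after``, at or before ``on_or_before``)."""
        hits = [
            ev.date
            for ev in self.coded_events
            if codes.matches(ev.code)
            and (after is None or ev.date > after)
            and (on_or_before is None or ev.date <= on_or_before)
        ]
        return min(hits) if hits else None

    def latest_lab(self, name: str, on_or_before: date) -> float | None:
        hits = [lab for lab in self.labs if lab.name == name and lab.date <= on_or_before]
        return max(hits, key=lambda lab: lab.date).value if hits else None


class CodeList:
    """A diagnosis/procedure code list with prefix wildcards."""

    def __init__(self, codes: Sequence[str]):
        if not codes:
            raise ValueError("code list must be non-empty")
        self.codes = [c.strip() for c in codes]
        self._exact = {c.upper() for c in self.codes if not c.endswith("*")}
        self._prefixes = tuple(c[:-1].upper() for c in self.codes if c.endswith("*"))

    def matches(self, code: str) -> bool:
        code = code.strip().upper()
        return code in self._exact or code.startswith(self._prefixes)


def _opt_date(value) -> date | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return date.fromisoformat(str(value).strip())


def _opt_float(value) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def read_registry(directory) -> dict[str, PatientRecord]:
    """Read the four registry tables from ``directory``.

    Expects ``patients.csv`` (patient_id, sex, birth_date, death_date,
    asian_flag, bmi, age_at_first_note — all but patient_id optional),
    and optional ``coded_events.csv`` (patient_id, code_system, code, date),
    ``procedures.csv`` (patient_id, code, date), ``labs.csv``
    (patient_id, name, value, date).
    """
    directory = Path(directory)
    pts = pd.read_csv(directory / "patients.csv", dtype=str, keep_default_na=False)
    records: dict[str, PatientRecord] = {}
    for row in pts.to_dict("records"):
        pid = row["patient_id"]
        records[pid] = PatientRecord(
            patient_id=pid,
            sex=row.get("sex") or None,
            birth_date=_opt_date(row.get("birth_date")),
            age_at_first_note=_opt_float(row.get("age_at_first_note")),
            death_date=_opt_date(row.get("death_date")),
            asian_flag=str(row.get("asian_flag", "")).lower() in ("1", "true", "yes"),
            bmi=_opt_float(row.get("bmi")),
        )

    ev_path = directory / "coded_events.csv"
    if ev_path.exists():
        for row in pd.read_csv(ev_path, dtype=str).to_dict("records"):
            records[row["patient_id"]].coded_events.append(
                CodedEvent(
                    code_system=row.get("code_system", "ICD"),
                    code=row["code"],
                    date=date.fromisoformat(row["date"]),
                )
            )
    proc_path = directory / "procedures.csv"
    if proc_path.exists():
        for row in pd.read_csv(proc_path, dtype=str).to_dict("records"):
            rec = records[row["patient_id"]]
            if row["code"].strip() == TRANSPLANT_CPT:
                rec.transplant_dates.append(date.fromisoformat(row["date"]))
        for rec in records.values():
            rec.transplant_dates.sort()
    lab_path = directory / "labs.csv"
    if lab_path.exists():
        for row in pd.read_csv(lab_path, dtype=str).to_dict("records"):
            records[row["patient_id"]].labs.append(
                LabResult(
                    name=row["name"],
                    value=float(row["value"]),
                    date=date.fromisoformat(row["date"]),
                )
            )
    return records


def write_registry(records: Iterable[PatientRecord], directory) -> None:
    """Write registry tables (inverse of :func:`read_registry`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = list(records)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sex": r.sex or "",
                "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                "age_at_first_note": r.age_at_first_note if r.age_at_first_note is not None else "",
                "death_date": r.death_date.isoformat() if r.death_date else "",
                "asian_flag": int(r.asian_flag),
                "bmi": r.bmi if r.bmi is not None else "",
            }
            for r in records
        ]
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "code_system": ev.code_system,
                "code": ev.code,
                "date": ev.date.isoformat(),
            }
            for r in records
            for ev in r.coded_events
        ],
        columns=["patient_id", "code_system", "code", "date"],
    ).to_csv(directory / "coded_events.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "code": TRANSPLANT_CPT, "date": d.isoformat()}
            for r in records
            for d in r.transplant_dates
        ],
        columns=["patient_id", "code", "date"],
    ).to_csv(directory / "procedures.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "name": lab.name,
                "value": lab.value,
                "date": lab.date.isoformat(),
            }
            for r in records
            for lab in r.labs
        ],
        columns=["patient_id", "name", "value", "date"],
    ).to_csv(directory / "labs.csv", index=False)
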