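"""Synthetic clinical notes and patient registries with known ground truth.

Real specialist notes cannot be redistributed, so every downstream module is
exercised on template-built hepatology notes and simulated registries whose
gold labels and event-generating rates are known exactly.  Template notes
contain an Assessment & Plan with either an affirmed MASH term, a term under
a negation trigger, or no term; a configurable fraction of notes omit
section headers entirely to exercise the whole-note fallback.  Templates
deliberately restrict themselves to phenomena the rule model covers (no
cross-sentence negation, no hedging games), so the detector's agreement with
the planted labels is expected to be exact; :data:`ADVERSARIAL_TEMPLATES`
collects constructions known to defeat the rules, for failure-mode tests.

Registry event times (death, transplant, incident cirrhosis coding) are
exponential at configured hazards measured from the index date — memoryless
and sufficient for incidence-rate recovery checks, not a claim about MASH
biology.  Default hazards, the baseline-cirrhosis fraction, and the
2012-2022 corpus window mirror a large single-centre MASH cohort.  Quota
mode plants exact numbers of exclusion conditions and baseline-cirrhosis
carriers for count-reproduction fixtures.

All randomness flows from ``SynthConfig.seed``; identical configs produce
identical corpora and registries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np

from .cohort import derive_index_date
from .notes import ClinicalNote
from .registry import CodedEvent, LabResult, PatientRecord

MASH_TERMS = (
    "NASH",
    "MASH",
    "nonalcoholic steatohepatitis",
    "metabolic dysfunction-associated steatohepatitis",
    "steatohepatitis",
)

POSITIVE_AP = (
    "1. {term} with compensated cirrhosis - continue vitamin E and weight loss counseling.\n2. Hypertension - continue lisinopril.",
    "Biopsy-proven {term}. Start lifestyle modification and repeat labs in 3 months.",
    "{term} cirrhosis, decompensated with ascites. Refer for transplant evaluation.",
    "Known {term}, clinically stable. Continue current management.",
)

NEGATED_AP = (
    "No evidence of {term} on biopsy. Continue monitoring liver enzymes.",
    "Imaging negative for {term}. Reassess in one year.",
    "{term} was ruled out by histology. Follow up as needed.",
    "Denies alcohol use; {term} unlikely. Repeat elastography in 12 months.",
)

CONTROL_AP = (
    "Hypertension, well controlled. Continue current therapy.",
    "Fatty liver on imaging without inflammation. Lifestyle advice given.",
    "Chronic hepatitis B, undetectable viral load. Continue tenofovir.",
)

#: Semantically negated constructions the rule model is known to affirm;
#: excluded from the conforming templates and from any agreement guarantee.
ADVERSARIAL_TEMPLATES = (
    # cross-sentence negation: the mention and its denial are in different sentences
    "{term} is a concern we discussed. There is no evidence of it on biopsy.",
    # trigger beyond the scope window (and phrased to miss the trigger lexicon)
    "No evidence on any of the many serial imaging studies obtained of {term}.",
)

_HEADERED_BODY = (
    "CC: follow-up.\n"
    "HPI: {age}-year-old patient seen in hepatology clinic for routine follow-up.\n"
    "Exam: no acute distress, soft abdomen.\n"
    "Assessment and Plan: {ap}"
)
_HEADERLESS_BODY = "Patient seen in clinic for routine follow-up. {ap}"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Hazards are events per person-year; the defaults match the incidence a
    large tertiary-centre MASH cohort reports (death 0.044/PY, incident
    cirrhosis 0.045/PY, transplant 0.031/PY), with 55.4% baseline cirrhosis
    and notes spanning 2012-2022 followed through the end of 2023.
    """

    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (1, 3)  # uniform inclusive range
    case_prevalence: float = 0.5
    positive_note_rate: float = 0.6  # extra notes of a case that are positive
    negated_mention_rate: float = 0.3  # among non-case notes
    headerless_note_rate: float = 0.1
    date_start: date = date(2012, 1, 1)
    date_end: date = date(2022, 12, 31)
    follow_up_end: date = date(2023, 12, 31)
    index_offset_days: int = 90
    death_rate: float = 0.044
    transplant_rate: float = 0.031
    cirrhosis_rate: float = 0.045
    baseline_cirrhosis_fraction: float = 1494 / 2695
    baseline_cirrhosis_exact: int | None = None
    decompensation_fraction: float = 917 / 1494
    exclusion_quota: Mapping[str, int] | None = None
    asian_fraction: float = 0.158
    missing_bmi_rate: float = 0.145
    seed: int = 0

    def __post_init__(self):
        for name in (
            "case_prevalence", "positive_note_rate", "negated_mention_rate",
            "headerless_note_rate", "baseline_cirrhosis_fraction",
            "decompensation_fraction", "asian_fraction", "missing_bmi_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("death_rate", "transplant_rate", "cirrhosis_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.date_start > self.date_end:
            raise ValueError("empty corpus date range")
        lo, hi = self.notes_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("notes_per_patient must be a 1-based inclusive range")


@dataclass
class NotesBundle:
    notes: list[ClinicalNote]
    gold_notes: dict[str, str]  # note_id -> mash_positive / mash_negative
    index_note_dates: dict[str, date | None]  # patient_id -> earliest positive


@dataclass
class RegistryBundle:
    records: dict[str, PatientRecord]
    planted_exclusions: dict[str, str]  # patient_id -> reason
    baseline_cirrhosis_ids: set[str] = field(default_factory=set)


def _random_date(rng: np.random.Generator, start: date, end: date) -> date:
    return start + timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def gen_notes(config: SynthConfig) -> NotesBundle:
    """Generate a note corpus with per-note gold labels.

    Each patient is a case with probability ``case_prevalence``; cases get at
    least one gold-positive note.  Non-case notes carry a negated mention at
    ``negated_mention_rate`` (keyword present but gold-negative), else no
    keyword at all.
    """
    rng = np.random.default_rng([config.seed, 1])
    notes: list[ClinicalNote] = []
    gold: dict[str, str] = {}
    index_dates: dict[str, date | None] = {}

    lo, hi = config.notes_per_patient
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        is_case = rng.random() < config.case_prevalence
        n_notes = int(rng.integers(lo, hi + 1))
        dates = sorted(
            _random_date(rng, config.date_start, config.date_end)
            for _ in range(n_notes)
        )
        if is_case:
            kinds = [
                "pos" if rng.random() < config.positive_note_rate else
                ("neg" if rng.random() < 0.5 else "ctl")
                for _ in range(n_notes)
            ]
            kinds[int(rng.integers(0, n_notes))] = "pos"  # guarantee >=1 positive
        else:
            kinds = [
                "neg" if rng.random() < config.negated_mention_rate else "ctl"
                for _ in range(n_notes)
            ]

        first_pos: date | None = None
        for j, (kind, when) in enumerate(zip(kinds, dates)):
            term = MASH_TERMS[int(rng.integers(0, len(MASH_TERMS)))]
            if kind == "pos":
                ap = POSITIVE_AP[int(rng.integers(0, len(POSITIVE_AP)))].format(term=term)
            elif kind == "neg":
                ap = NEGATED_AP[int(rng.integers(0, len(NEGATED_AP)))].format(term=term)
            else:
                ap = CONTROL_AP[int(rng.integers(0, len(CONTROL_AP)))]
            headerless = rng.random() < config.headerless_note_rate
            age = int(rng.integers(25, 86))
            text = (
                _HEADERLESS_BODY.format(ap=ap)
                if headerless
                else _HEADERED_BODY.format(age=age, ap=ap)
            )
            note_id = f"{pid}-N{j:02d}"
            notes.append(
                ClinicalNote(
                    note_id=note_id,
                    patient_id=pid,
                    note_date=when,
                    specialty="hepatology",
                    text=text,
                )
            )
            gold[note_id] = "mash_positive" if kind == "pos" else "mash_negative"
            if kind == "pos" and (first_pos is None or when < first_pos):
                first_pos = when
        index_dates[pid] = first_pos
    return NotesBundle(notes=notes, gold_notes=gold, index_note_dates=index_dates)


def _normalize_quota(quota: Mapping[str, int] | None) -> dict[str, int]:
    if not quota:
        return {}
    quota = dict(quota)
    if "total" in quota:
        total = quota.pop("total")
        if quota:
            raise ValueError("use either 'total' or per-reason quotas, not both")
        base, rem = divmod(total, 3)
        kinds = ("death_before_index", "transplant_before_index", "missing_age_or_sex")
        quota = {k: base + (1 if i < rem else 0) for i, k in enumerate(kinds)}
    allowed = {
        "death_before_index",
        "transplant_before_index",
        "mash_after_transplant",
        "missing_age_or_sex",
    }
    bad = set(quota) - allowed
    if bad:
        raise ValueError(f"unknown exclusion-quota keys: {sorted(bad)}")
    if any(v < 0 for v in quota.values()):
        raise ValueError("quota counts must be non-negative")
    return {k: v for k, v in quota.items() if v > 0}


def _exp_days(rng: np.random.Generator, rate: float) -> int | None:
    """Exponential waiting time in whole days (>= 1), or None at rate 0."""
    if rate <= 0:
        return None
    return int(rng.exponential(1.0 / rate) * 365.25) + 1


def gen_registry(config: SynthConfig, cases: Mapping[str, date | None]) -> RegistryBundle:
    """Generate PatientRecords for NLP-flagged patients.

    ``cases`` maps patient_id to the earliest positive note date (None for
    non-cases, who get demographics only).  Event times are exponential at
    the configured hazards measured from each case's index date.  Quota mode
    plants exact counts of exclusion conditions; baseline-cirrhosis carriers
    (exact count or Bernoulli fraction) are drawn from patients *without* a
    planted exclusion so quota arithmetic composes.
    """
    rng = np.random.default_rng([config.seed, 2])
    pids = sorted(cases)
    case_pids = [p for p in pids if cases[p] is not None]

    quota = _normalize_quota(config.exclusion_quota)
    n_quota = sum(quota.values())
    if n_quota > len(case_pids):
        raise ValueError(
            f"exclusion quota ({n_quota}) exceeds the {len(case_pids)} flagged patients"
        )
    chosen = rng.choice(len(case_pids), size=n_quota, replace=False) if n_quota else []
    planted: dict[str, str] = {}
    it = iter(chosen)
    for reason, count in sorted(quota.items()):
        for _ in range(count):
            planted[case_pids[int(next(it))]] = reason

    clean_pids = [p for p in case_pids if p not in planted]
    if config.baseline_cirrhosis_exact is not None:
        k = config.baseline_cirrhosis_exact
        if k > len(clean_pids):
            raise ValueError(
                f"baseline_cirrhosis_exact ({k}) exceeds the {len(clean_pids)} "
                "patients without planted exclusions"
            )
        idx = rng.choice(len(clean_pids), size=k, replace=False)
        cirr_ids = {clean_pids[int(i)] for i in idx}
    else:
        cirr_ids = {
            p for p in clean_pids if rng.random() < config.baseline_cirrhosis_fraction
        }

    records: dict[str, PatientRecord] = {}
    missing_toggle = 0
    for pid in pids:
        note_date = cases[pid]
        sex = "female" if rng.random() < 0.537 else "male"
        bmi = float(np.clip(rng.normal(31.0, 6.0), 16.0, 60.0))
        if rng.random() < config.missing_bmi_rate:
            bmi = None
        asian = rng.random() < config.asian_fraction

        if note_date is None:
            anchor = _random_date(rng, config.date_start, config.date_end)
            birth = anchor - timedelta(days=int(rng.integers(25, 86)) * 365 + int(rng.integers(0, 365)))
            records[pid] = PatientRecord(
                patient_id=pid, sex=sex, birth_date=birth, asian_flag=asian, bmi=bmi
            )
            continue

        index_date = derive_index_date(note_date, config.index_offset_days)
        age = int(rng.integers(25, 86))
        birth = index_date - timedelta(days=age * 365 + int(rng.integers(0, 365)))

        rec = PatientRecord(
            patient_id=pid, sex=sex, birth_date=birth, asian_flag=asian, bmi=bmi
        )
        lab_date = index_date - timedelta(days=14)
        rec.labs = [
            LabResult("bilirubin", round(float(rng.lognormal(np.log(0.9), 0.5)), 2), lab_date),
            LabResult("sodium", round(float(np.clip(rng.normal(138, 2.5), 122, 148)), 1), lab_date),
            LabResult("inr", round(float(rng.lognormal(np.log(1.1), 0.15)), 2), lab_date),
            LabResult("creatinine", round(float(rng.lognormal(np.log(0.85), 0.3)), 2), lab_date),
            LabResult("albumin", round(float(np.clip(rng.normal(3.8, 0.5), 1.5, 5.0)), 2), lab_date),
        ]

        d = _exp_days(rng, config.death_rate)
        if d is not None:
            rec.death_date = index_date + timedelta(days=d)
        t = _exp_days(rng, config.transplant_rate)
        if t is not None:
            rec.transplant_dates = [index_date + timedelta(days=t)]
        c = _exp_days(rng, config.cirrhosis_rate)
        if c is not None and pid not in cirr_ids:
            rec.coded_events.append(
                CodedEvent("ICD", "K74.60", index_date + timedelta(days=c))
            )

        if pid in cirr_ids:
            rec.coded_events.append(
                CodedEvent("ICD", "K74.60", note_date - timedelta(days=30))
            )
            if rng.random() < config.decompensation_fraction:
                rec.coded_events.append(
                    CodedEvent("ICD", "R18.8", note_date - timedelta(days=20))
                )

        reason = planted.get(pid)
        if reason == "death_before_index":
            rec.death_date = index_date - timedelta(days=10)
        elif reason == "transplant_before_index":
            rec.transplant_dates = sorted(
                rec.transplant_dates + [index_date - timedelta(days=30)]
            )
        elif reason == "mash_after_transplant":
            rec.transplant_dates = sorted(
                rec.transplant_dates + [note_date - timedelta(days=50)]
            )
        elif reason == "missing_age_or_sex":
            if missing_toggle % 2 == 0:
                rec.sex = None
            else:
                rec.birth_date = None
                rec.age_at_first_note = None
            missing_toggle += 1

        records[pid] = rec
    return RegistryBundle(
        records=records,
        planted_exclusions=planted,
        baseline_cirrhosis_ids=cirr_ids,
    )


def simulate(config: SynthConfig) -> tuple[NotesBundle, RegistryBundle]:
    """Generate a matched corpus and registry in one call."""
    nb = gen_notes(config)
    rb = gen_registry(config, nb.index_note_dates)
    return nb, rb
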