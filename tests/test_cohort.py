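"""Index dating, exclusions, subcohorts, MELD 3.0, BMI categories,
time-to-event tables, and incidence arithmetic."""

from datetime import date, timedelta

import pytest

from mashcohort import (
    CodeList,
    CodedEvent,
    LabResult,
    PatientRecord,
    apply_exclusions,
    assign_subcohort,
    bmi_category,
    build_tte,
    derive_index_date,
    incidence_rate,
    meld3,
    summarize_tte,
)
from mashcohort.cohort import (
    ALL_CAUSE_MORTALITY,
    CENSORED_ADMIN,
    CENSORED_COMPETING,
    CIRRHOSIS,
    EVENT,
    INCIDENT_CIRRHOSIS,
    LIVER_TRANSPLANT,
    NO_CIRRHOSIS,
    person_years,
)

CIRR = CodeList(["K74.6*", "K74.3"])
FUP = date(2023, 12, 31)


def _record(pid="p1", **kw):
    defaults = dict(sex="female", birth_date=date(1970, 1, 1))
    defaults.update(kw)
    return PatientRecord(patient_id=pid, **defaults)


class TestIndexDate:
    @pytest.mark.parametrize(
        "start, offset, expected",
        [
            (date(2018, 3, 1), 90, date(2018, 5, 30)),
            (date(2019, 12, 15), 90, date(2020, 3, 14)),  # across leap day
            (date(2018, 12, 15), 90, date(2019, 3, 15)),  # same span, no leap day
            (date(2020, 2, 29), 90, date(2020, 5, 29)),  # leap-day start
            (date(2021, 7, 4), 0, date(2021, 7, 4)),
        ],
    )
    def test_calendar_offset(self, start, offset, expected):
        assert derive_index_date(start, offset) == expected

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            derive_index_date(date(2020, 1, 1), -1)


class TestExclusions:
    NOTE = date(2018, 1, 1)
    INDEX = date(2018, 4, 1)  # note + 90

    def _run(self, record):
        return apply_exclusions({record.patient_id: self.NOTE}, {record.patient_id: record})[0]

    def test_death_before_index(self):
        e = self._run(_record(death_date=self.INDEX - timedelta(days=10)))
        assert e.exclusion_reason == "death_before_index"

    def test_death_after_index_included(self):
        e = self._run(_record(death_date=self.INDEX + timedelta(days=1)))
        assert e.included

    def test_transplant_before_index(self):
        e = self._run(_record(transplant_dates=[self.INDEX - timedelta(days=30)]))
        assert e.exclusion_reason == "transplant_before_index"

    def test_transplant_years_after_index_included(self):
        e = self._run(_record(transplant_dates=[self.INDEX + timedelta(days=730)]))
        assert e.included

    def test_mash_after_transplant_distinct_reason(self):
        # transplant precedes even the index *note*: the diagnosis itself
        # post-dates the graft, recorded under its own reason
        e = self._run(_record(transplant_dates=[self.NOTE - timedelta(days=50)]))
        assert e.exclusion_reason == "mash_after_transplant"

    def test_missing_sex(self):
        assert self._run(_record(sex=None)).exclusion_reason == "missing_age_or_sex"

    def test_missing_age(self):
        e = self._run(_record(birth_date=None, age_at_first_note=None))
        assert e.exclusion_reason == "missing_age_or_sex"

    def test_minor_excluded(self):
        e = self._run(_record(birth_date=date(2005, 1, 1)))
        assert e.exclusion_reason == "age_under_18"

    def test_partition_every_candidate_once(self):
        records = {
            "a": _record("a"),
            "b": _record("b", death_date=self.INDEX - timedelta(days=1)),
            "c": _record("c", sex=None),
        }
        entries = apply_exclusions({p: self.NOTE for p in records}, records)
        assert sorted(e.patient_id for e in entries) == ["a", "b", "c"]
        assert sum(e.included for e in entries) == 1
        assert all((e.exclusion_reason is None) == e.included for e in entries)

    def test_death_checked_before_transplant(self):
        e = self._run(
            _record(
                death_date=self.INDEX - timedelta(days=5),
                transplant_dates=[self.INDEX - timedelta(days=40)],
            )
        )
        assert e.exclusion_reason == "death_before_index"


class TestSubcohort:
    NOTE = date(2018, 1, 1)

    def _entry(self, record):
        return apply_exclusions({record.patient_id: self.NOTE}, {record.patient_id: record})[0]

    def test_code_on_index_date_counts_as_baseline(self):
        rec = _record(coded_events=[CodedEvent("ICD", "K74.60", date(2018, 4, 1))])
        e = assign_subcohort(self._entry(rec), rec, CIRR)
        assert e.subcohort == CIRRHOSIS

    def test_code_after_index_not_baseline(self):
        rec = _record(coded_events=[CodedEvent("ICD", "K74.60", date(2018, 4, 2))])
        e = assign_subcohort(self._entry(rec), rec, CIRR)
        assert e.subcohort == NO_CIRRHOSIS

    def test_no_codes(self):
        rec = _record()
        assert assign_subcohort(self._entry(rec), rec, CIRR).subcohort == NO_CIRRHOSIS

    def test_wildcard_prefix_match(self):
        assert CIRR.matches("K74.69")
        assert CIRR.matches("k74.60")
        assert not CIRR.matches("K74.0")
        assert CIRR.matches("K74.3")

    def test_decompensation_flag(self):
        decomp = CodeList(["R18.8"])
        rec = _record(
            coded_events=[
                CodedEvent("ICD", "K74.60", date(2017, 1, 1)),
                CodedEvent("ICD", "R18.8", date(2017, 6, 1)),
            ]
        )
        e = assign_subcohort(self._entry(rec), rec, CIRR, decomp)
        assert e.subcohort == CIRRHOSIS and e.decompensated is True


class TestBmiCategory:
    @pytest.mark.parametrize(
        "bmi, asian, expected",
        [
            (18.4, False, "underweight"),
            (18.4, True, "underweight"),
            (18.5, False, "normal"),
            (22.9, True, "normal"),
            (23.0, True, "overweight"),
            (24.9, False, "normal"),
            (25.0, False, "overweight"),
            (27.4, True, "overweight"),
            (27.5, True, "obese"),
            (27.5, False, "overweight"),
            (29.9, False, "overweight"),
            (30.0, False, "obese"),
            (None, False, "missing"),
        ],
    )
    def test_cut_points(self, bmi, asian, expected):
        assert bmi_category(bmi, asian) == expected

    def test_nonpositive_bmi_rejected(self):
        with pytest.raises(ValueError):
            bmi_category(0.0)


class TestMeld3:
    def test_neutral_male_is_intercept(self):
        assert meld3("male", 1.0, 137, 1.0, 1.0, 3.5) == 6.43

    def test_female_additive_term(self):
        assert meld3("female", 1.0, 137, 1.0, 1.0, 3.5) == pytest.approx(7.76)

    def test_sodium_clamped_low(self):
        assert meld3("male", 1.0, 120, 1.0, 1.0, 3.5) == meld3("male", 1.0, 125, 1.0, 1.0, 3.5)

    def test_creatinine_capped(self):
        assert meld3("male", 1.0, 137, 1.0, 5.0, 3.5) == meld3("male", 1.0, 137, 1.0, 3.0, 3.5)

    def test_floors(self):
        assert meld3("male", 0.4, 137, 0.9, 0.6, 3.5) == 6.43

    def test_missing_input_gives_missing_score(self):
        assert meld3("male", None, 137, 1.0, 1.0, 3.5) is None

    def test_higher_bilirubin_raises_score(self):
        assert meld3("male", 4.0, 137, 1.0, 1.0, 3.5) > meld3("male", 1.0, 137, 1.0, 1.0, 3.5)


def _included_entry(record, note=date(2018, 1, 1), cirr=CIRR):
    (e,) = apply_exclusions({record.patient_id: note}, {record.patient_id: record})
    assert e.included
    return assign_subcohort(e, record, cirr)


class TestBuildTte:
    def test_death_event_time(self):
        rec = _record(death_date=date(2018, 12, 31))
        e = _included_entry(rec, note=date(2017, 10, 3))  # index 2018-01-01
        (row,) = build_tte([e], {rec.patient_id: rec}, ALL_CAUSE_MORTALITY, FUP)
        assert row.status == EVENT and row.time_days == 364

    def test_no_events_admin_censored(self):
        rec = _record()
        e = _included_entry(rec)
        (row,) = build_tte([e], {rec.patient_id: rec}, ALL_CAUSE_MORTALITY, FUP)
        assert row.status == CENSORED_ADMIN
        assert row.time_days == (FUP - e.index_date).days

    def test_death_competes_with_transplant(self):
        rec = _record(
            coded_events=[CodedEvent("ICD", "K74.60", date(2017, 1, 1))],
            death_date=date(2019, 6, 1),
        )
        e = _included_entry(rec)
        assert e.subcohort == CIRRHOSIS
        (row,) = build_tte([e], {rec.patient_id: rec}, LIVER_TRANSPLANT, FUP, cirrhosis_codes=CIRR)
        assert row.status == CENSORED_COMPETING
        assert row.time_days == (date(2019, 6, 1) - e.index_date).days

    def test_outcome_within_guard_after_competing_still_event(self):
        # transplant recorded 30 days after death: delayed recording, counts
        rec = _record(
            coded_events=[CodedEvent("ICD", "K74.60", date(2017, 1, 1))],
            death_date=date(2019, 6, 1),
            transplant_dates=[date(2019, 7, 1)],
        )
        e = _included_entry(rec)
        (row,) = build_tte([e], {rec.patient_id: rec}, LIVER_TRANSPLANT, FUP, cirrhosis_codes=CIRR)
        assert row.status == EVENT

    def test_guard_zero_censors_strictly(self):
        rec = _record(
            coded_events=[CodedEvent("ICD", "K74.60", date(2017, 1, 1))],
            death_date=date(2019, 6, 1),
            transplant_dates=[date(2019, 7, 1)],
        )
        e = _included_entry(rec)
        (row,) = build_tte(
            [e], {rec.patient_id: rec}, LIVER_TRANSPLANT, FUP, cirrhosis_codes=CIRR, guard_days=0
        )
        assert row.status == CENSORED_COMPETING

    def test_incident_cirrhosis_on_no_cirrhosis_subcohort(self):
        rec = _record(coded_events=[CodedEvent("ICD", "K74.60", date(2020, 5, 5))])
        e = _included_entry(rec)
        assert e.subcohort == NO_CIRRHOSIS
        (row,) = build_tte([e], {rec.patient_id: rec}, INCIDENT_CIRRHOSIS, FUP, cirrhosis_codes=CIRR)
        assert row.status == EVENT
        assert row.time_days == (date(2020, 5, 5) - e.index_date).days

    def test_subcohort_mismatch_rejected(self):
        rec = _record(coded_events=[CodedEvent("ICD", "K74.60", date(2017, 1, 1))])
        e = _included_entry(rec)  # cirrhosis subcohort
        with pytest.raises(ValueError, match="subcohort"):
            build_tte([e], {rec.patient_id: rec}, INCIDENT_CIRRHOSIS, FUP, cirrhosis_codes=CIRR)

    def test_outcome_on_index_date_drops_from_risk_set(self):
        rec = _record(death_date=date(2018, 4, 1))
        (e,) = apply_exclusions({rec.patient_id: date(2018, 1, 1)}, {rec.patient_id: rec})
        assert e.included  # death is *on* the index date, not before it
        rows = build_tte([e], {rec.patient_id: rec}, ALL_CAUSE_MORTALITY, FUP)
        assert rows == []

    def test_event_after_follow_up_end_is_censored(self):
        rec = _record(death_date=FUP + timedelta(days=5))
        e = _included_entry(rec)
        (row,) = build_tte([e], {rec.patient_id: rec}, ALL_CAUSE_MORTALITY, FUP)
        assert row.status == CENSORED_ADMIN

    def test_time_bounds(self):
        recs = {
            "a": _record("a", death_date=date(2020, 1, 1)),
            "b": _record("b"),
        }
        entries = [_included_entry(recs[p], note=date(2018, 1, 1)) for p in recs]
        for row in build_tte(entries, recs, ALL_CAUSE_MORTALITY, FUP):
            idx = date(2018, 4, 1)
            assert 0 <= row.time_days <= (FUP - idx).days


class TestIncidence:
    @pytest.mark.parametrize(
        "events, py, expected",
        [(529, 11904.7, 4.4), (231, 5104.4, 4.5), (166, 5341.9, 3.1)],
    )
    def test_per_100_py(self, events, py, expected):
        assert round(incidence_rate(events, py), 1) == expected

    def test_zero_events(self):
        assert incidence_rate(0, 123.4) == 0.0

    def test_nonpositive_py_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)

    def test_summary_consistent_with_rows(self):
        recs = {
            "a": _record("a", death_date=date(2019, 1, 1)),
            "b": _record("b"),
            "c": _record("c", death_date=date(2021, 6, 1)),
        }
        entries = [_included_entry(recs[p]) for p in recs]
        rows = build_tte(entries, recs, ALL_CAUSE_MORTALITY, FUP)
        s = summarize_tte(rows)
        n_events = sum(1 for r in rows if r.status == EVENT)
        assert s["n_events"] == n_events == 2
        assert s["rate_per_100py"] == round(
            incidence_rate(n_events, person_years(rows)), 2
        )
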