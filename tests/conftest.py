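from datetime import date

import pytest

from mashcohort import Lexicon, NegationRules
from mashcohort.synth import SynthConfig, gen_notes, simulate


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.from_config()


@pytest.fixture(scope="session")
def rules():
    return NegationRules.from_config()


@pytest.fixture(scope="session")
def small_bundle():
    """A small matched corpus + registry used across modules."""
    return simulate(SynthConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def small_corpus(small_bundle):
    return small_bundle[0]


def ap_note(text, note_id="n1", patient_id="p1", when=date(2020, 6, 1)):
    """A one-liner note whose A&P is exactly ``text``."""
    from mashcohort import ClinicalNote

    return ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        note_date=when,
        specialty="hepatology",
        text="HPI: routine follow-up.\nAssessment and Plan: " + text,
    )
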