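"""Keyword detector with NegEx-style assertion classification.

A note is MASH-positive iff its Assessment & Plan contains at least one
lexicon mention that is not negated.  Mentions come from word-boundary regex
matching (leftmost-longest, non-overlapping); assertion status comes from
trigger phrases scoped within the mention's sentence: a pre-trigger ("no
evidence of") before the mention, or a post-trigger ("is ruled out") after
it, negates the mention when it lies within ``scope_window`` content tokens
and no terminator ("but", ";") intervenes.  Hedged mentions ("possible
NASH") count as affirmed unless a trigger fires — the detector models
presence/absence only, not uncertainty or historicity.

Patient-level classification takes the earliest positive note as the index
note, the anchor from which the cohort index date is later derived.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Sequence

from .config import read_yaml
from .notes import (
    ClinicalNote,
    NoteSection,
    Sentence,
    extract_ap_section,
    split_sentences,
)

AFFIRMED = "affirmed"
NEGATED = "negated"
MASH_POSITIVE = "mash_positive"
MASH_NEGATIVE = "mash_negative"

_WORDLIKE = re.compile(r"\w")


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    label: str = "mash"
    case_sensitive: bool = False


class Lexicon:
    """Compiled keyword lexicon; every pattern is wrapped in word boundaries."""

    def __init__(self, entries: Sequence[LexiconEntry]):
        if not entries:
            raise ValueError("lexicon must be non-empty")
        self.entries = list(entries)
        self._compiled: list[tuple[re.Pattern, LexiconEntry]] = []
        for entry in self.entries:
            flags = 0 if entry.case_sensitive else re.IGNORECASE
            pat = re.compile(r"\b(?:%s)\b" % entry.pattern, flags)
            if pat.match(""):
                raise ValueError(f"lexicon pattern matches empty string: {entry.pattern!r}")
            self._compiled.append((pat, entry))

    @classmethod
    def from_config(cls, path=None) -> "Lexicon":
        data = read_yaml(path, default="lexicon.yml")
        entries = [
            LexiconEntry(
                pattern=e["pattern"],
                label=e.get("label", "mash"),
                case_sensitive=bool(e.get("case_sensitive", False)),
            )
            for e in data.get("entries", [])
        ]
        return cls(entries)

    def finditer(self, text: str):
        for pat, entry in self._compiled:
            for m in pat.finditer(text):
                yield m.start(), m.end(), entry


@dataclass(frozen=True)
class NegationRules:
    """NegEx-style trigger lists with a token scope window."""

    pre_triggers: tuple[str, ...]
    post_triggers: tuple[str, ...]
    terminators: tuple[str, ...]
    scope_window: int = 6

    def __post_init__(self):
        if self.scope_window < 0:
            raise ValueError("scope_window must be >= 0")

    @classmethod
    def from_config(cls, path=None) -> "NegationRules":
        data = read_yaml(path, default="negation.yml")
        return cls(
            pre_triggers=tuple(data.get("pre_triggers", [])),
            post_triggers=tuple(data.get("post_triggers", [])),
            terminators=tuple(data.get("terminators", [])),
            scope_window=int(data.get("scope_window", 6)),
        )


def _phrase_pattern(phrase: str) -> re.Pattern:
    # word-boundary anchoring only where the phrase edge is word-like,
    # so punctuation triggers like ";" still match
    esc = re.escape(phrase)
    left = r"\b" if _WORDLIKE.match(phrase[0]) else ""
    right = r"\b" if _WORDLIKE.match(phrase[-1]) else ""
    return re.compile(left + esc + right, re.IGNORECASE)


@dataclass(frozen=True)
class Mention:
    """A lexicon hit; the span is note-level, half-open."""

    note_id: str
    sentence_ordinal: int
    text: str
    start: int
    end: int
    label: str
    assertion: str | None = None


@dataclass(frozen=True)
class NoteLabel:
    note_id: str
    patient_id: str
    note_date: date
    label: str
    mentions: tuple[Mention, ...] = ()


@dataclass(frozen=True)
class PatientFlag:
    """Patient-level result: case status and the earliest positive note date."""

    patient_id: str
    is_case: bool
    index_note_date: date | None = None


def find_mentions(
    section: NoteSection,
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
) -> list[Mention]:
    """Return non-overlapping leftmost-longest lexicon matches.

    When entries overlap (e.g. "steatohepatitis" inside "nonalcoholic
    steatohepatitis") the match starting earliest wins; on equal starts the
    longer match wins.  Spans are note-level; assertion is left unset.
    """
    mentions: list[Mention] = []
    for sent in sentences:
        candidates = [
            (s, e, entry) for s, e, entry in lexicon.finditer(sent.text)
        ]
        candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
        taken_end = -1
        for s, e, entry in candidates:
            if s < taken_end:
                continue
            taken_end = e
            abs_start = section.start_offset + sent.start + s
            abs_end = section.start_offset + sent.start + e
            mentions.append(
                Mention(
                    note_id=section.note_id,
                    sentence_ordinal=sent.ordinal,
                    text=sent.text[s:e],
                    start=abs_start,
                    end=abs_end,
                    label=entry.label,
                )
            )
    return mentions


def _content_tokens(text: str) -> int:
    """Count whitespace-delimited tokens that carry at least one word character."""
    return sum(1 for tok in text.split() if _WORDLIKE.search(tok))


def _scope_clear(between: str, rules: NegationRules, terminators: list[re.Pattern]) -> bool:
    if _content_tokens(between) > rules.scope_window:
        return False
    return not any(t.search(between) for t in terminators)


def classify_assertion(
    mention: Mention,
    sentence: Sentence,
    rules: NegationRules,
    section_offset: int = 0,
) -> Mention:
    """Set the mention's assertion to affirmed or negated.

    A pre-trigger negates when it ends before the mention with at most
    ``scope_window`` content tokens and no terminator between; post-triggers
    mirror this after the mention.  Anything else is affirmed.
    """
    rel_start = mention.start - section_offset - sentence.start
    rel_end = mention.end - section_offset - sentence.start
    if not (0 <= rel_start <= rel_end <= len(sentence.text)):
        raise ValueError("mention does not lie within the given sentence")
    stext = sentence.text
    terminators = [_phrase_pattern(t) for t in rules.terminators]

    for phrase in rules.pre_triggers:
        for m in _phrase_pattern(phrase).finditer(stext):
            if m.end() <= rel_start and _scope_clear(
                stext[m.end() : rel_start], rules, terminators
            ):
                return replace(mention, assertion=NEGATED)
    for phrase in rules.post_triggers:
        for m in _phrase_pattern(phrase).finditer(stext):
            if m.start() >= rel_end and _scope_clear(
                stext[rel_end : m.start()], rules, terminators
            ):
                return replace(mention, assertion=NEGATED)
    return replace(mention, assertion=AFFIRMED)


def classify_note(
    note: ClinicalNote,
    lexicon: Lexicon,
    rules: NegationRules,
    header_patterns: Sequence[str] | None = None,
    boundary_patterns: Sequence[str] | None = None,
) -> NoteLabel:
    """Full per-note pipeline: section -> sentences -> mentions -> assertions.

    The note is labelled ``mash_positive`` iff at least one mention is
    affirmed; empty or section-less notes are ``mash_negative``.
    """
    section = extract_ap_section(note, header_patterns, boundary_patterns)
    sentences = split_sentences(section)
    raw = find_mentions(section, sentences, lexicon)
    classified = tuple(
        classify_assertion(m, sentences[m.sentence_ordinal], rules, section.start_offset)
        for m in raw
    )
    label = (
        MASH_POSITIVE
        if any(m.assertion == AFFIRMED for m in classified)
        else MASH_NEGATIVE
    )
    return NoteLabel(
        note_id=note.note_id,
        patient_id=note.patient_id,
        note_date=note.note_date,
        label=label,
        mentions=classified,
    )


def classify_patients(labels: Iterable[NoteLabel]) -> dict[str, PatientFlag]:
    """Aggregate note labels to patients.

    A patient is a case iff any note is positive; the index note date is the
    earliest positive note date (ties broken by lexicographic note_id, which
    cannot change the date).
    """
    best: dict[str, tuple[date, str] | None] = {}
    for lab in labels:
        best.setdefault(lab.patient_id, None)
        if lab.label == MASH_POSITIVE:
            key = (lab.note_date, lab.note_id)
            if best[lab.patient_id] is None or key < best[lab.patient_id]:
                best[lab.patient_id] = key
    return {
        pid: PatientFlag(
            patient_id=pid,
            is_case=found is not None,
            index_note_date=found[0] if found else None,
        )
        for pid, found in best.items()
    }
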