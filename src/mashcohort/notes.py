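"""Clinical-note model: corpus reading, Assessment & Plan sectioning, and
sentence segmentation.

The detector only scans the Assessment & Plan (A&P) — the section where the
clinician commits to diagnoses — so locating it reliably matters more than
parsing the rest of the note.  Sectioning is purely pattern-based: an ordered
list of case-insensitive A&P header regexes anchors the section start, and
the next header from a broader section-header inventory (or end of note)
terminates it.  Notes without a recognizable A&P header fall back to scanning
the whole note rather than being dropped, which favours sensitivity.

All character offsets are 0-based, half-open, so ``text[start:end]`` always
round-trips the stored section/sentence text.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .config import default_ap_headers, default_section_headers

logger = logging.getLogger(__name__)

ASSESSMENT_AND_PLAN = "assessment_and_plan"
WHOLE_NOTE_FALLBACK = "whole_note_fallback"

#: Abbreviations whose trailing period never ends a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr.", "mr.", "mrs.", "ms.", "vs.", "st.", "jr.", "sr.",
        "e.g.", "i.e.", "etc.", "approx.", "pt.", "dx.", "hx.", "tx.",
        "q.d.", "b.i.d.", "t.i.d.", "p.o.", "prn.",
    }
)

_LIST_MARKER = r"(?:[-*•]|\d+[.)])"


@dataclass(frozen=True)
class ClinicalNote:
    """A dated free-text specialist note."""

    note_id: str
    patient_id: str
    note_date: date
    specialty: str = ""
    text: str = ""


@dataclass(frozen=True)
class NoteSection:
    """A located segment of a note; offsets are note-level, half-open."""

    note_id: str
    section_name: str
    start_offset: int
    end_offset: int
    text: str

    def __post_init__(self):
        if not (0 <= self.start_offset <= self.end_offset):
            raise ValueError("invalid section offsets")


@dataclass(frozen=True)
class Sentence:
    """A sentence within a section; offsets are section-relative."""

    start: int
    end: int
    ordinal: int
    text: str


class CorpusError(ValueError):
    """A per-record corpus problem (missing field, bad date)."""

    def __init__(self, message: str, note_id: str | None = None):
        super().__init__(message)
        self.note_id = note_id


def _parse_record(rec: dict, lineno: int, corpus_end: date | None) -> ClinicalNote:
    note_id = rec.get("note_id") or None
    for key in ("patient_id", "note_id", "note_date", "text"):
        if rec.get(key) in (None, ""):
            # empty text is legal; only a missing key is not
            if key == "text" and "text" in rec:
                continue
            raise CorpusError(
                f"record {lineno}: missing required field '{key}'", note_id
            )
    try:
        note_date = date.fromisoformat(str(rec["note_date"]).strip())
    except ValueError as exc:
        raise CorpusError(
            f"record {lineno}: unparseable note_date {rec['note_date']!r}: {exc}",
            note_id,
        ) from None
    if corpus_end is not None and note_date > corpus_end:
        raise CorpusError(
            f"record {lineno}: note_date {note_date} is after the corpus end "
            f"date {corpus_end}",
            note_id,
        )
    return ClinicalNote(
        note_id=str(rec["note_id"]),
        patient_id=str(rec["patient_id"]),
        note_date=note_date,
        specialty=str(rec.get("specialty") or ""),
        text=str(rec.get("text") or ""),
    )


def read_corpus(
    path,
    format: str = "delimited_table",
    *,
    on_error: str = "raise",
    corpus_end: date | None = None,
) -> list[ClinicalNote]:
    """Read a note corpus from a CSV table or JSON Lines file.

    Parameters
    ----------
    path
        File with columns/keys ``patient_id, note_id, note_date, text``
        (``specialty`` optional); dates ISO-8601.
    format
        ``"delimited_table"`` (comma-separated, UTF-8, header row) or
        ``"json_lines"``.
    on_error
        ``"raise"`` aborts on the first bad record; ``"skip"`` logs the
        record (with its note_id when available) and continues.
    corpus_end
        Optional corpus end date; notes dated after it (i.e. in the future
        relative to the extract) are treated as bad records.

    Record order is preserved.
    """
    if format not in ("delimited_table", "json_lines"):
        raise ValueError(f"unknown corpus format {format!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")

    path = Path(path)
    notes: list[ClinicalNote] = []
    with path.open(encoding="utf-8", newline="") as fh:
        if format == "delimited_table":
            records: Iterable[dict] = csv.DictReader(fh)
        else:
            records = (json.loads(line) for line in fh if line.strip())
        for lineno, rec in enumerate(records, start=1):
            try:
                notes.append(_parse_record(rec, lineno, corpus_end))
            except CorpusError as exc:
                if on_error == "raise":
                    raise
                logger.warning("skipping corpus record: %s", exc)
    return notes


def _compile(patterns: Sequence[str], *, line_anchor: bool = False) -> list[re.Pattern]:
    flags = re.IGNORECASE
    if line_anchor:
        return [re.compile(r"(?m)^[ \t]*(?:%s)" % p, flags) for p in patterns]
    return [re.compile(p, flags) for p in patterns]


def extract_ap_section(
    note: ClinicalNote,
    header_patterns: Sequence[str] | None = None,
    boundary_patterns: Sequence[str] | None = None,
) -> NoteSection:
    """Locate the Assessment & Plan section of a note.

    Header patterns are tried in order; for the first pattern that matches,
    the *last* occurrence anchors the section (the A&P conventionally closes
    a note).  The section runs from the end of the header match to the next
    recognized section header (from the full ``boundary_patterns`` inventory)
    or the end of the note.  If nothing matches, the whole note is returned
    with ``section_name=whole_note_fallback`` — header-less notes are scanned
    rather than discarded.
    """
    headers = _compile(header_patterns or default_ap_headers())
    boundaries = _compile(
        boundary_patterns or default_section_headers(), line_anchor=True
    )
    text = note.text
    if not text:
        return NoteSection(note.note_id, WHOLE_NOTE_FALLBACK, 0, 0, "")

    for pat in headers:
        matches = list(pat.finditer(text))
        if not matches:
            continue
        m = matches[-1]
        start = m.end()
        while start < len(text) and text[start].isspace():
            start += 1
        end = len(text)
        for bpat in boundaries:
            bm = bpat.search(text, start)
            if bm is not None and bm.start() < end:
                end = bm.start()
        while end > start and text[end - 1].isspace():
            end -= 1
        return NoteSection(note.note_id, ASSESSMENT_AND_PLAN, start, end, text[start:end])
    return NoteSection(note.note_id, WHOLE_NOTE_FALLBACK, 0, len(text), text)


def split_sentences(
    section: NoteSection,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Segment a section into sentences.

    Boundaries are sentence-final punctuation (``. ! ?`` followed by
    whitespace or end of text) and list-item starts (a newline followed by a
    bullet or numbering marker).  Periods belonging to known abbreviations or
    to a line-initial list number ("1.") do not split.  Offsets are
    section-relative; whitespace between sentences belongs to neither.
    """
    text = section.text
    if not text.strip():
        return []

    breaks: set[int] = set()
    for m in re.finditer(r"[.!?]+(?=\s|$)", text):
        j = m.start()
        while j > 0 and not text[j - 1].isspace():
            j -= 1
        word = text[j : m.end()]
        if word.lower() in abbreviations:
            continue
        at_line_start = j == 0 or text[j - 1] == "\n"
        if at_line_start and re.fullmatch(r"\d+[.)]", word):
            continue  # list numbering, not a sentence end
        breaks.add(m.end())
    for m in re.finditer(r"\n(?=[ \t]*%s(?:\s|$))" % _LIST_MARKER, text):
        breaks.add(m.start())

    bounds = sorted(breaks | {0, len(text)})
    sentences: list[Sentence] = []
    for lo, hi in zip(bounds, bounds[1:]):
        start, end = lo, hi
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if start == end:
            continue
        sentences.append(
            Sentence(start=start, end=end, ordinal=len(sentences), text=text[start:end])
        )
    return sentences
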