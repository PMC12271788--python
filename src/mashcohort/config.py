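"""Loaders for the editable rule files (lexicon, negation rules, header
patterns, code lists).

All rule inputs are plain text so that a clinical informaticist can tune the
detector without touching code: YAML for the lexicon and negation rules,
one-regex-per-line files for header patterns, one-code-per-line files for
ICD/CPT code lists.  ``#`` starts a comment in the line-oriented formats.
Defaults ship inside the package under ``mashcohort/data``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml


def _default_path(name: str):
    return resources.files("mashcohort").joinpath("data", name)


def read_pattern_file(path=None, *, default: str | None = None) -> list[str]:
    """Read a one-regex-per-line pattern file; '#' comments and blanks skipped."""
    if path is None:
        if default is None:
            raise ValueError("either a path or a packaged default is required")
        text = _default_path(default).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(line)
    return patterns


def read_code_file(path=None, *, default: str | None = None) -> list[str]:
    """Read a one-code-per-line code list (trailing ``*`` = prefix wildcard)."""
    return read_pattern_file(path, default=default)


def read_yaml(path=None, *, default: str | None = None) -> dict:
    if path is None:
        if default is None:
            raise ValueError("either a path or a packaged default is required")
        text = _default_path(default).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at top level of {path or default}")
    return data


def default_ap_headers() -> list[str]:
    return read_pattern_file(default="ap_headers.txt")


def default_section_headers() -> list[str]:
    return read_pattern_file(default="section_headers.txt")


def default_cirrhosis_codes() -> list[str]:
    return read_code_file(default="cirrhosis_codes.txt")


def default_decompensation_codes() -> list[str]:
    return read_code_file(default="decompensation_codes.txt")
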