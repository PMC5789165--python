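"""Clinical text preprocessing.

Four small, deterministic steps feed the extractors: mapping free-text
document titles onto the ten corpus document types, abbreviation-safe
sentence segmentation, tokenization that keeps "35%" as one token, and
section segmentation driven by an editable header-dialect table.

Section headers vary wildly between facilities, so the header table is a
plain TSV shipped with the package (``data/section_headers.tsv``) and can be
replaced wholesale via :func:`load_header_table` / the CLI.  "IMPRESSION:"
maps to the echocardiogram narrative-summary section inside echocardiogram
reports and to the assessment section everywhere else — the narrative
summary is where the reviewing cardiologist's EF statement lives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .types import DocType, SectionLabel, SectionSpan, SentenceSpan

# --- document-type mapping -------------------------------------------------

# Ordered: first matching pattern wins.  "MEDICATION RECONCILIATION" must be
# tested before "DISCHARGE" so a discharge med-recon form maps to pharmacy.
_DOC_TYPE_PATTERNS: list[tuple[re.Pattern, DocType]] = [
    (re.compile(p, re.I), t)
    for p, t in [
        (r"MEDICATION\s+RECONCIL|MED\s+RECON", DocType.PHARMACY_MED_RECON),
        (r"ECHO", DocType.ECHOCARDIOGRAM),
        (r"CARDIOLOG.*CONSULT|CONSULT.*CARDIOLOG|\bCARDIOLOGY\b", DocType.CARDIOLOGY_CONSULT),
        (r"DISCHARGE\s+SUMMAR", DocType.DISCHARGE_SUMMARY),
        (r"PHARMAC", DocType.PHARMACY_OTHER),
        (r"CONSULT", DocType.CONSULT_OTHER),
        (r"HISTORY\s*(&|AND)\s*PHYSICAL|\bH\s*&\s*P\b", DocType.HISTORY_AND_PHYSICAL),
        (r"PROGRESS", DocType.PROGRESS_NOTE),
        (r"NURS", DocType.NURSING_NOTE),
    ]
]


def map_document_type(title: str) -> DocType:
    """Map a free-text document title onto one of the ten document types.

    Matching is case-insensitive keyword matching; anything unrecognized
    falls into the other (general) catch-all, so the function is total.
    """
    for pattern, doc_type in _DOC_TYPE_PATTERNS:
        if pattern.search(title or ""):
            return doc_type
    return DocType.OTHER_GENERAL


# --- sentence segmentation -------------------------------------------------

# Common clinical abbreviations that end with a period but do not end a
# sentence.  Dotted shorthand like "b.i.d." is caught structurally below.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
    "vs", "etc", "approx", "appt",
    "e.g", "i.e", "eg", "ie",
    "mg", "mcg", "ml", "tab", "cap", "po", "pt", "hx", "dx", "tx", "fx",
    "b.i.d", "t.i.d", "q.i.d", "q.d", "q.h.s", "p.o", "p.r.n", "s.l",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")


def _is_abbreviation(prefix: str) -> bool:
    m = re.search(r"(\S+)$", prefix)
    if m is None:
        return False
    token = m.group(1).rstrip(".").lower()
    if token in _ABBREVIATIONS:
        return True
    # dotted shorthand such as "b.i.d" / "q.8.h"
    if re.fullmatch(r"(?:[A-Za-z0-9]\.)+[A-Za-z0-9]?", m.group(1)):
        return True
    # single initial, e.g. "John Q."
    if re.fullmatch(r"[A-Z]", m.group(1)):
        return True
    return False


def split_sentences(text: str) -> list[SentenceSpan]:
    """Split note text into ordered, non-overlapping sentence spans.

    Newlines are hard boundaries (clinical notes are line-oriented); within a
    line, ``.``/``!``/``?`` followed by whitespace ends a sentence unless the
    preceding token is a known or dotted abbreviation.  Spans are trimmed to
    non-whitespace content and together cover every non-whitespace character.
    """
    spans: list[SentenceSpan] = []
    offset = 0
    for line in text.split("\n"):
        start = 0
        for m in _BOUNDARY.finditer(line):
            if _is_abbreviation(line[: m.start()]):
                continue
            spans.extend(_trimmed(line, start, m.end(), offset))
            start = m.end()
        spans.extend(_trimmed(line, start, len(line), offset))
        offset += len(line) + 1
    return spans


def _trimmed(line: str, start: int, end: int, offset: int) -> list[SentenceSpan]:
    chunk = line[start:end]
    stripped = chunk.strip()
    if not stripped:
        return []
    lead = len(chunk) - len(chunk.lstrip())
    return [
        SentenceSpan(offset + start + lead, offset + start + lead + len(stripped))
    ]


def sentence_for(spans: Sequence[SentenceSpan], pos: int) -> Optional[SentenceSpan]:
    """The sentence span containing character position ``pos``, if any."""
    for s in spans:
        if s.start <= pos < s.end:
            return s
    return None


# --- tokenization ----------------------------------------------------------

_TOKEN = re.compile(r"\d+(?:\.\d+)?%|\d+(?:\.\d+)?|\w+|[^\w\s]")


def tokenize(text: str) -> list[tuple[int, int]]:
    """Token spans; numbers keep attached percent signs ("35%" is one token)."""
    return [(m.start(), m.end()) for m in _TOKEN.finditer(text)]


# --- section segmentation --------------------------------------------------


@dataclass(frozen=True)
class HeaderRule:
    label: SectionLabel
    pattern: re.Pattern
    doc_types: Optional[frozenset]  # None = applies to all document types

    def applies_to(self, doc_type: DocType) -> bool:
        return self.doc_types is None or doc_type in self.doc_types


def load_header_table(path: str | Path) -> list[HeaderRule]:
    """Load a header-dialect table (label <TAB> regex <TAB> doc_types)."""
    rules: list[HeaderRule] = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{i}: expected 3 tab-separated fields")
        label, pattern, doc_types = parts
        rules.append(
            HeaderRule(
                label=SectionLabel(label.strip()),
                pattern=re.compile(pattern.strip(), re.I),
                doc_types=None
                if doc_types.strip() == "*"
                else frozenset(DocType(t.strip()) for t in doc_types.split(",")),
            )
        )
    return rules


def default_header_table() -> list[HeaderRule]:
    with resources.as_file(
        resources.files("hfquality.data") / "section_headers.tsv"
    ) as p:
        return load_header_table(p)


_DEFAULT_TABLE: Optional[list[HeaderRule]] = None


def _table() -> list[HeaderRule]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = default_header_table()
    return _DEFAULT_TABLE


def segment_sections(
    text: str,
    doc_type: DocType = DocType.OTHER_GENERAL,
    table: Optional[Sequence[HeaderRule]] = None,
) -> list[SectionSpan]:
    """Segment a note into labelled sections using the header table.

    Every character belongs to exactly one section; text before the first
    recognized header (or a headerless note) is labelled ``other``.  The
    function is total: it never fails, and identical input yields identical
    spans.
    """
    if table is None:
        table = _table()
    if not text:
        return []

    headers: list[tuple[int, SectionLabel]] = []
    offset = 0
    for line in text.split("\n"):
        for rule in table:
            if rule.applies_to(doc_type) and rule.pattern.match(line):
                headers.append((offset, rule.label))
                break
        offset += len(line) + 1

    sections: list[SectionSpan] = []
    if not headers or headers[0][0] > 0:
        first = headers[0][0] if headers else len(text)
        sections.append(SectionSpan(SectionLabel.OTHER, 0, first))
    for i, (start, label) in enumerate(headers):
        end = headers[i + 1][0] if i + 1 < len(headers) else len(text)
        if end > start:
            sections.append(SectionSpan(label, start, end))
    return sections


def section_for(sections: Sequence[SectionSpan], pos: int) -> SectionLabel:
    for s in sections:
        if s.start <= pos < s.end:
            return s.label
    return SectionLabel.OTHER


__all__ = [
    "HeaderRule",
    "default_header_table",
    "load_header_table",
    "map_document_type",
    "section_for",
    "segment_sections",
    "sentence_for",
    "split_sentences",
    "tokenize",
]
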