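"""Deterministic concept extractors.

Three concept families are extracted from note text:

* **EF mentions** — any trigger ("EF", "LVEF", "ejection fraction",
  "systolic function") plus, where present, a normalized value: a point
  percentage, a range (normalized to its midpoint), a comparative bound
  ("EF > 55%" keeps its direction), or a qualitative severity phrase.
* **ACEI/ARB mentions** — case-insensitive word-boundary matches against an
  editable lexicon of generic names, brands, and class-level phrases, each
  normalized to generic name + drug class.
* **RNM mentions** — documented reasons an ACEI/ARB was not prescribed
  (allergy, angioedema, hyperkalemia, renal dysfunction, hypotension,
  refusal, comfort care, other).  A reason phrase is only emitted when its
  sentence also references an ACEI/ARB or carries a stop/avoid trigger, so
  "potassium normal" in a lab comment never becomes an RNM.

Context assertion is a trigger-and-scope rule in the NegEx tradition:
negation ("not on", "denies", "no") and discontinuation ("held", "stopped",
"discontinued", "allergic to") triggers govern mentions within the same
sentence up to a conjunction boundary.

Extraction is idempotent and deterministic, and mention spans never overlap
within one concept type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .preprocess import section_for, segment_sections, split_sentences
from .types import (
    ClinicalNote,
    Concept,
    ConceptMention,
    DrugClass,
    EFValue,
    MedMatch,
    QualitativeEF,
    RNMCategory,
    SectionSpan,
    SentenceSpan,
)

# --- medication lexicon ----------------------------------------------------


@dataclass(frozen=True)
class MedLexiconEntry:
    generic: str
    drug_class: DrugClass
    variants: tuple[str, ...]  # brands / abbreviations, lowercase


class MedLexicon:
    """Surface-form → generic-name lookup for ACEI/ARB mentions."""

    # Class-level phrases resolve to a class but no specific generic.
    CLASS_PATTERNS: list[tuple[str, DrugClass]] = [
        (r"angiotensin[- ]converting[- ]enzyme\s+inhibitors?", DrugClass.ACEI),
        (r"angiotensin[- ]receptor\s+blockers?", DrugClass.ARB),
        (r"ace[- ]inhibitors?", DrugClass.ACEI),
        (r"ace-?is?", DrugClass.ACEI),
        (r"arbs?", DrugClass.ARB),
    ]

    def __init__(self, entries: Sequence[MedLexiconEntry]):
        self.entries = list(entries)
        seen: dict[str, str] = {}
        self._by_surface: dict[str, MedLexiconEntry] = {}
        for entry in self.entries:
            for surface in (entry.generic, *entry.variants):
                s = surface.lower()
                if s in seen and seen[s] != entry.generic:
                    raise ValueError(
                        f"lexicon surface {surface!r} maps to both "
                        f"{seen[s]!r} and {entry.generic!r}"
                    )
                seen[s] = entry.generic
                self._by_surface[s] = entry
        drug_alts = sorted(self._by_surface, key=len, reverse=True)
        parts = [re.escape(s) for s in drug_alts]
        parts += [p for p, _ in self.CLASS_PATTERNS]
        self._pattern = re.compile(
            r"\b(?:" + "|".join(parts) + r")\b", re.I
        )
        self._class_res = [
            (re.compile(r"\b(?:%s)\b" % p, re.I), c) for p, c in self.CLASS_PATTERNS
        ]

    def lookup(self, surface: str) -> Optional[MedMatch]:
        entry = self._by_surface.get(surface.lower())
        if entry is not None:
            return MedMatch(generic=entry.generic, drug_class=entry.drug_class)
        for pattern, drug_class in self._class_res:
            if pattern.fullmatch(surface):
                return MedMatch(generic=None, drug_class=drug_class)
        return None

    def finditer(self, text: str):
        return self._pattern.finditer(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "MedLexicon":
        entries = []
        for i, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected generic<TAB>class[<TAB>variants]")
            generic, drug_class = parts[0].strip(), DrugClass(parts[1].strip())
            variants = tuple(
                v.strip().lower()
                for v in (parts[2].split(",") if len(parts) > 2 else [])
                if v.strip()
            )
            entries.append(MedLexiconEntry(generic.lower(), drug_class, variants))
        return cls(entries)

    @classmethod
    def default(cls) -> "MedLexicon":
        with resources.as_file(
            resources.files("hfquality.data") / "acei_arb_lexicon.tsv"
        ) as p:
            return cls.from_file(p)


_DEFAULT_LEXICON: Optional[MedLexicon] = None


def default_lexicon() -> MedLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = MedLexicon.default()
    return _DEFAULT_LEXICON


# --- EF parsing ------------------------------------------------------------

EF_TRIGGER = re.compile(
    r"\b(?:LV\s?EF|EF|ejection\s+fraction|"
    r"(?:left\s+ventricular\s+|LV\s+)?systolic\s+function)\b",
    re.I,
)

_NUM = r"(\d{1,3}(?:\.\d+)?)"
# value patterns tried in order within the post-trigger window
_RANGE = re.compile(rf"{_NUM}\s*(?:-|–|\bto\b)\s*{_NUM}\s*%", re.I)
_COMPARATIVE = re.compile(rf"(<|>|<=|>=|≤|≥)\s*{_NUM}\s*%")
_POINT = re.compile(rf"{_NUM}\s*(?:%|percent\b)", re.I)

_QUALITATIVE: list[tuple[re.Pattern, QualitativeEF]] = [
    (re.compile(p, re.I), label)
    for p, label in [
        (r"\bseverely\s+(?:reduced|depressed|decreased|impaired)\b", QualitativeEF.SEVERELY_REDUCED),
        (r"\bmoderately\s+(?:reduced|depressed|decreased|impaired)\b", QualitativeEF.MODERATELY_REDUCED),
        (r"\bmildly\s+(?:reduced|depressed|decreased|impaired)\b", QualitativeEF.MILDLY_REDUCED),
        (r"\b(?:low[- ])?normal\b", QualitativeEF.NORMAL_OR_PRESERVED),
        (r"\bpreserved\b", QualitativeEF.NORMAL_OR_PRESERVED),
        (r"\bhyperdynamic\b", QualitativeEF.NORMAL_OR_PRESERVED),
    ]
]

_DIRECTIONS = {"<": "lt", "<=": "le", "≤": "le", ">": "gt", ">=": "ge", "≥": "ge"}

# how far past the trigger to look for a value / qualitative phrase
_VALUE_WINDOW = 60
_QUAL_BACK_WINDOW = 40


def _find_value_after(
    text: str, pos: int
) -> Optional[tuple[EFValue, int, int]]:
    """Parse the first EF value in ``text[pos:pos + window]``.

    Returns (value, start, end) in coordinates of ``text``, or None.
    """
    window = text[pos : pos + _VALUE_WINDOW]
    # stop at sentence-ish boundaries so a value in the next statement is
    # not attributed to this trigger
    cut = re.search(r"[.;\n]", window)
    if cut:
        window = window[: cut.end()]
    m = _RANGE.search(window)
    if m:
        low, high = float(m.group(1)), float(m.group(2))
        if 0 <= low < high <= 100:
            return EFValue.range(low, high), pos + m.start(), pos + m.end()
    m = _COMPARATIVE.search(window)
    if m:
        v = float(m.group(2))
        if 0 <= v <= 100:
            return (
                EFValue.point(v, direction=_DIRECTIONS[m.group(1)]),
                pos + m.start(),
                pos + m.end(),
            )
    m = _POINT.search(window)
    if m:
        v = float(m.group(1))
        if 0 <= v <= 100:
            return EFValue.point(v), pos + m.start(), pos + m.end()
    return None


def _find_qualitative(text: str, trig_start: int, trig_end: int):
    lo = max(0, trig_start - _QUAL_BACK_WINDOW)
    back_breaks = list(re.finditer(r"[.;\n]", text[lo:trig_start]))
    if back_breaks:  # do not reach into the previous sentence
        lo += back_breaks[-1].end()
    hi = trig_end + _VALUE_WINDOW
    cut = re.search(r"[.;\n]", text[trig_end:hi])
    if cut:
        hi = trig_end + cut.end()
    window = text[lo:hi]
    for pattern, label in _QUALITATIVE:
        m = pattern.search(window)
        if m:
            return EFValue.qualitative(label), lo + m.start(), lo + m.end()
    return None


def parse_ef_value(snippet: str) -> Optional[EFValue]:
    """Parse the EF value carried by a snippet containing an EF trigger.

    Returns None when the trigger has no resolvable value (the mention still
    counts as an EF mention; whether it counts toward "LVSF assessed" is a
    classification-config decision).
    """
    trig = EF_TRIGGER.search(snippet)
    if trig is None:
        return None
    found = _find_value_after(snippet, trig.end())
    if found:
        return found[0]
    qual = _find_qualitative(snippet, trig.start(), trig.end())
    if qual:
        return qual[0]
    return None


def extract_ef_mentions(
    note: ClinicalNote, sections: Optional[Sequence[SectionSpan]] = None
) -> list[ConceptMention]:
    """One EF mention per trigger occurrence, in document order.

    The mention span runs from the trigger to the end of the parsed value
    (or just the trigger when no value is found).  Overlapping triggers
    ("LVEF (EF) 35%") collapse onto the first.
    """
    if sections is None:
        sections = segment_sections(note.text, note.doc_type)
    mentions: list[ConceptMention] = []
    last_end = -1
    for trig in EF_TRIGGER.finditer(note.text):
        if trig.start() < last_end:
            continue
        found = _find_value_after(note.text, trig.end())
        if found:
            value, _, v_end = found
            start, end = trig.start(), v_end
        else:
            qual = _find_qualitative(note.text, trig.start(), trig.end())
            if qual:
                value, q_start, q_end = qual
                start, end = min(trig.start(), q_start), max(trig.end(), q_end)
            else:
                value, start, end = None, trig.start(), trig.end()
        mentions.append(
            ConceptMention(
                concept=Concept.EF_MENTION,
                note_id=note.note_id,
                start=start,
                end=end,
                value=value,
                section=section_for(sections, start),
            )
        )
        last_end = end
    return mentions


# --- medication extraction -------------------------------------------------


def extract_med_mentions(
    note: ClinicalNote,
    lexicon: Optional[MedLexicon] = None,
    sections: Optional[Sequence[SectionSpan]] = None,
) -> list[ConceptMention]:
    """Word-boundary lexicon matches, each normalized to generic + class."""
    if lexicon is None:
        lexicon = default_lexicon()
    if sections is None:
        sections = segment_sections(note.text, note.doc_type)
    mentions: list[ConceptMention] = []
    last_end = -1
    for m in lexicon.finditer(note.text):
        if m.start() < last_end:
            continue
        match = lexicon.lookup(m.group(0))
        if match is None:  # pragma: no cover - pattern and lookup share sources
            continue
        mentions.append(
            ConceptMention(
                concept=Concept.ACEI_ARB,
                note_id=note.note_id,
                start=m.start(),
                end=m.end(),
                value=match,
                section=section_for(sections, m.start()),
            )
        )
        last_end = m.end()
    return mentions


# --- context assertion -----------------------------------------------------

_NEGATION_PRE = re.compile(
    r"\b(?:no|not|denies|denied|without|never|neither|nor|negative\s+for)\b", re.I
)
_DISCONTINUED = re.compile(
    r"\b(?:discontinu\w+|stop(?:ped|ping|s)?|held|hold(?:ing)?|d/?c'?d?|"
    r"withheld|withhold(?:ing)?|allerg(?:y|ic)\s+to|off|"
    r"contraindicat\w+|refus\w+|declin\w+|unable\s+to\s+tolerate|"
    r"not\s+a\s+candidate)\b",
    re.I,
)
_CONDITIONAL = re.compile(
    r"\b(?:if|unless|consider(?:ing)?|would|may\s+start|pending)\b", re.I
)
# scope terminators: a new clause releases the trigger's governance
_CLAUSE_BREAK = re.compile(r"\b(?:but|however|although|though|except)\b|[;:]", re.I)


def _pre_scope(sentence: str, rel_start: int) -> str:
    pre = sentence[:rel_start]
    breaks = list(_CLAUSE_BREAK.finditer(pre))
    if breaks:
        pre = pre[breaks[-1].end() :]
    return pre


def _post_scope(sentence: str, rel_end: int) -> str:
    post = sentence[rel_end:]
    brk = _CLAUSE_BREAK.search(post)
    if brk:
        post = post[: brk.start()]
    return post


def assert_context(
    mention: ConceptMention,
    sentence_text: str,
    sentence_start: int = 0,
) -> ConceptMention:
    """Set negated/discontinued/conditional flags from the enclosing sentence.

    A negation trigger preceding the mention within its clause negates it; a
    discontinuation trigger on either side within the clause marks it
    discontinued; conditional markers anywhere in the pre-scope mark it
    conditional.  The mention is mutated and returned.
    """
    rel_start = mention.start - sentence_start
    rel_end = mention.end - sentence_start
    pre = _pre_scope(sentence_text, rel_start)
    post = _post_scope(sentence_text, rel_end)
    if _DISCONTINUED.search(pre) or _DISCONTINUED.search(post):
        mention.discontinued = True
    if _NEGATION_PRE.search(pre):
        mention.negated = True
    if _CONDITIONAL.search(pre):
        mention.conditional = True
    return mention


def assert_context_all(
    mentions: Sequence[ConceptMention],
    text: str,
    sentences: Optional[Sequence[SentenceSpan]] = None,
) -> list[ConceptMention]:
    if sentences is None:
        sentences = split_sentences(text)
    for mention in mentions:
        sent = next(
            (s for s in sentences if s.start <= mention.start < s.end), None
        )
        if sent is not None:
            assert_context(mention, text[sent.start : sent.end], sent.start)
    return list(mentions)


# --- RNM extraction --------------------------------------------------------


@dataclass(frozen=True)
class RNMTrigger:
    category: RNMCategory
    pattern: re.Pattern


def load_rnm_triggers(path: str | Path) -> list[RNMTrigger]:
    triggers: list[RNMTrigger] = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected category<TAB>regex")
        triggers.append(
            RNMTrigger(RNMCategory(parts[0].strip()), re.compile(parts[1].strip(), re.I))
        )
    return triggers


def default_rnm_triggers() -> list[RNMTrigger]:
    with resources.as_file(
        resources.files("hfquality.data") / "rnm_triggers.tsv"
    ) as p:
        return load_rnm_triggers(p)


_DEFAULT_RNM: Optional[list[RNMTrigger]] = None


def _rnm_table() -> list[RNMTrigger]:
    global _DEFAULT_RNM
    if _DEFAULT_RNM is None:
        _DEFAULT_RNM = default_rnm_triggers()
    return _DEFAULT_RNM


# a stop/avoid trigger licenses a reason phrase even without a drug mention
_STOP_AVOID = re.compile(
    r"\b(?:held|hold|stopp?\w*|discontinu\w+|contraindicat\w+|avoid\w*|"
    r"withheld|unable\s+to\s+tolerate|not\s+a\s+candidate|do\s+not\s+(?:start|give)|"
    r"cannot\s+(?:take|tolerate))\b",
    re.I,
)


def extract_rnm_mentions(
    note: ClinicalNote,
    triggers: Optional[Sequence[RNMTrigger]] = None,
    lexicon: Optional[MedLexicon] = None,
    sections: Optional[Sequence[SectionSpan]] = None,
    sentences: Optional[Sequence[SentenceSpan]] = None,
) -> list[ConceptMention]:
    """Reasons-no-medication mentions, one per reason phrase.

    A reason phrase is emitted only when its sentence also references an
    ACEI/ARB (lexicon or class term) or carries a stop/avoid trigger.  When
    a sentence holds both a specific category (e.g. hyperkalemia) and the
    generic "contraindicated" phrase, only the specific category is emitted.
    """
    if triggers is None:
        triggers = _rnm_table()
    if lexicon is None:
        lexicon = default_lexicon()
    if sections is None:
        sections = segment_sections(note.text, note.doc_type)
    if sentences is None:
        sentences = split_sentences(note.text)

    mentions: list[ConceptMention] = []
    for sent in sentences:
        stext = note.text[sent.start : sent.end]
        hits: list[tuple[RNMCategory, int, int]] = []
        for trigger in triggers:
            for m in trigger.pattern.finditer(stext):
                hits.append((trigger.category, m.start(), m.end()))
        if not hits:
            continue
        has_med_ref = next(lexicon.finditer(stext), None) is not None
        if not has_med_ref and not _STOP_AVOID.search(stext):
            continue
        specific = [h for h in hits if h[0] is not RNMCategory.OTHER_DOCUMENTED_REASON]
        chosen = specific if specific else hits
        chosen.sort(key=lambda h: h[1])
        last_end = -1
        for category, start, end in chosen:
            if start < last_end:
                continue
            mentions.append(
                ConceptMention(
                    concept=Concept.RNM,
                    note_id=note.note_id,
                    start=sent.start + start,
                    end=sent.start + end,
                    value=category,
                    section=section_for(sections, sent.start + start),
                )
            )
            last_end = end
    return mentions


__all__ = [
    "EF_TRIGGER",
    "MedLexicon",
    "MedLexiconEntry",
    "RNMTrigger",
    "assert_context",
    "assert_context_all",
    "default_lexicon",
    "default_rnm_triggers",
    "extract_ef_mentions",
    "extract_med_mentions",
    "extract_rnm_mentions",
    "load_rnm_triggers",
    "parse_ef_value",
]
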