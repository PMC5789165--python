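"""Core domain types for the pipeline.

The object model mirrors how inpatient heart-failure quality review actually
works: free-text notes grouped per discharge, concept-level evidence (ejection
fraction statements, ACEI/ARB medication mentions, documented reasons not to
prescribe), and a per-patient roll-up that feeds the CHI19 measure logic
(LVEF documented; if LVEF <40%, an ACEI or ARB at discharge unless a reason
not to is documented).

Character offsets are 0-based and half-open, counted in the note body after
newline normalization to ``\\n``, so ``text[start:end]`` always reproduces the
evidence span.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Iterator, Optional


class DocType(str, enum.Enum):
    """The ten document types a VA-style inpatient corpus is mapped onto."""

    HISTORY_AND_PHYSICAL = "history_and_physical"
    PROGRESS_NOTE = "progress_note"
    CARDIOLOGY_CONSULT = "cardiology_consult"
    ECHOCARDIOGRAM = "echocardiogram"
    PHARMACY_MED_RECON = "pharmacy_med_recon"
    PHARMACY_OTHER = "pharmacy_other"
    CONSULT_OTHER = "consult_other"
    DISCHARGE_SUMMARY = "discharge_summary"
    NURSING_NOTE = "nursing_note"
    OTHER_GENERAL = "other_general"


class SectionLabel(str, enum.Enum):
    ASSESSMENT = "assessment"
    CURRENT_HISTORY = "current_history"
    MEDICATIONS = "medications"
    ECHO_RESULTS = "echo_results"
    ECHO_NARRATIVE_SUMMARY = "echo_narrative_summary"
    OTHER = "other"


class Concept(str, enum.Enum):
    EF_MENTION = "EF_MENTION"
    ACEI_ARB = "ACEI_ARB"
    RNM = "RNM"


class DrugClass(str, enum.Enum):
    ACEI = "ACEI"
    ARB = "ARB"


class QualitativeEF(str, enum.Enum):
    NORMAL_OR_PRESERVED = "normal_or_preserved"
    MILDLY_REDUCED = "mildly_reduced"
    MODERATELY_REDUCED = "moderately_reduced"
    SEVERELY_REDUCED = "severely_reduced"
    UNKNOWN = "unknown"


class RNMCategory(str, enum.Enum):
    """Documented reasons an ACEI/ARB was not prescribed."""

    ALLERGY_INTOLERANCE = "allergy_intolerance"
    ANGIOEDEMA = "angioedema"
    HYPERKALEMIA = "hyperkalemia"
    RENAL_DYSFUNCTION = "renal_dysfunction"
    HYPOTENSION = "hypotension"
    PATIENT_REFUSAL = "patient_refusal"
    COMFORT_CARE = "comfort_care"
    OTHER_DOCUMENTED_REASON = "other_documented_reason"


class Classification(str, enum.Enum):
    MET = "MET"
    NOT_MET = "NOT_MET"


@dataclass(frozen=True)
class EFValue:
    """A normalized left-ventricular ejection fraction statement.

    ``form`` is one of ``point``, ``range``, ``qualitative``.  Comparative
    expressions such as "EF > 55%" are points at the bound with ``direction``
    set ("gt"/"ge"/"lt"/"le"), so directionality survives normalization:
    "EF > 55%" can never satisfy an <40% threshold while "EF < 20%" always
    does.
    """

    form: str
    low: Optional[float] = None
    high: Optional[float] = None
    qualitative_label: Optional[QualitativeEF] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form not in ("point", "range", "qualitative"):
            raise ValueError(f"unknown EFValue form: {self.form!r}")
        if self.form == "point":
            if self.low is None or self.low != self.high:
                raise ValueError("point EFValue requires low == high")
            _check_percent(self.low)
        elif self.form == "range":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError("range EFValue requires low < high")
            _check_percent(self.low)
            _check_percent(self.high)
        else:
            if self.qualitative_label is None:
                raise ValueError("qualitative EFValue requires a label")

    @property
    def representative(self) -> Optional[float]:
        """Point value, range midpoint, or None for qualitative statements."""
        if self.form == "point":
            return self.low
        if self.form == "range":
            return (self.low + self.high) / 2.0
        return None

    def is_below(self, threshold: float, strict: bool = True) -> Optional[bool]:
        """Whether this EF establishes being below ``threshold``.

        Returns True/False when the statement settles the question and None
        when it does not (mildly-reduced or unknown qualitative labels, or a
        comparative bound that straddles the threshold).
        """
        if self.form == "qualitative":
            if self.qualitative_label in (
                QualitativeEF.SEVERELY_REDUCED,
                QualitativeEF.MODERATELY_REDUCED,
            ):
                return True
            if self.qualitative_label is QualitativeEF.NORMAL_OR_PRESERVED:
                return False
            return None
        rep = self.representative
        if self.direction in ("gt", "ge"):
            # true EF >= bound
            below = rep < threshold if strict else rep <= threshold
            return False if not below else None
        if self.direction in ("lt", "le"):
            # true EF <= bound
            below = rep < threshold if strict else rep <= threshold
            return True if below else None
        return rep < threshold if strict else rep <= threshold

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "low": self.low,
            "high": self.high,
            "qualitative_label": self.qualitative_label.value
            if self.qualitative_label
            else None,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EFValue":
        return cls(
            form=d["form"],
            low=d.get("low"),
            high=d.get("high"),
            qualitative_label=QualitativeEF(d["qualitative_label"])
            if d.get("qualitative_label")
            else None,
            direction=d.get("direction"),
        )

    @classmethod
    def point(cls, value: float, direction: Optional[str] = None) -> "EFValue":
        return cls(form="point", low=value, high=value, direction=direction)

    @classmethod
    def range(cls, low: float, high: float) -> "EFValue":
        return cls(form="range", low=low, high=high)

    @classmethod
    def qualitative(cls, label: QualitativeEF) -> "EFValue":
        return cls(form="qualitative", qualitative_label=label)


def _check_percent(v: float) -> None:
    if not 0 <= v <= 100:
        raise ValueError(f"EF percent out of [0, 100]: {v}")


@dataclass(frozen=True)
class MedMatch:
    """A medication mention normalized to its generic name and class.

    ``generic`` is None for class-level references ("an ACE inhibitor").
    """

    generic: Optional[str]
    drug_class: DrugClass

    def to_dict(self) -> dict:
        return {"generic": self.generic, "drug_class": self.drug_class.value}

    @classmethod
    def from_dict(cls, d: dict) -> "MedMatch":
        return cls(generic=d.get("generic"), drug_class=DrugClass(d["drug_class"]))


@dataclass
class ClinicalNote:
    note_id: str
    patient_id: str
    note_datetime: Optional[datetime]
    title: str
    text: str
    doc_type: DocType = DocType.OTHER_GENERAL

    def __post_init__(self) -> None:
        if self.text is None:
            raise ValueError(f"note {self.note_id}: text may be empty but not null")
        # Normalize newlines so character offsets are platform independent.
        self.text = self.text.replace("\r\n", "\n").replace("\r", "\n")

    @property
    def sort_key(self) -> tuple:
        # Undated notes sort before all dated notes (affects "most recent").
        return (self.note_datetime is not None, self.note_datetime or datetime.min)


@dataclass(frozen=True)
class SectionSpan:
    label: SectionLabel
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad section span [{self.start}, {self.end})")


@dataclass(frozen=True)
class SentenceSpan:
    start: int
    end: int


@dataclass
class ConceptMention:
    """A located concept with its normalized payload and context flags."""

    concept: Concept
    note_id: str
    start: int
    end: int
    value: object = None  # EFValue | MedMatch | RNMCategory | None
    negated: bool = False
    discontinued: bool = False
    conditional: bool = False
    section: SectionLabel = SectionLabel.OTHER

    def to_dict(self) -> dict:
        if isinstance(self.value, EFValue):
            value = {"ef": self.value.to_dict()}
        elif isinstance(self.value, MedMatch):
            value = {"med": self.value.to_dict()}
        elif isinstance(self.value, RNMCategory):
            value = {"rnm": self.value.value}
        else:
            value = None
        return {
            "concept": self.concept.value,
            "note_id": self.note_id,
            "start": self.start,
            "end": self.end,
            "value": value,
            "negated": self.negated,
            "discontinued": self.discontinued,
            "conditional": self.conditional,
            "section": self.section.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptMention":
        raw = d.get("value")
        value: object = None
        if raw:
            if "ef" in raw:
                value = EFValue.from_dict(raw["ef"])
            elif "med" in raw:
                value = MedMatch.from_dict(raw["med"])
            elif "rnm" in raw:
                value = RNMCategory(raw["rnm"])
        return cls(
            concept=Concept(d["concept"]),
            note_id=d["note_id"],
            start=d["start"],
            end=d["end"],
            value=value,
            negated=d.get("negated", False),
            discontinued=d.get("discontinued", False),
            conditional=d.get("conditional", False),
            section=SectionLabel(d.get("section", "other")),
        )


@dataclass
class PatientDeterminations:
    """Per-patient rolled-up facts plus the CHI19 classification."""

    patient_id: str
    lvsf_assessed: bool
    ef: Optional[EFValue]
    ef_lt_40: Optional[bool]  # None = documented but indeterminate
    on_acei_arb: bool
    rnm_present: bool
    classification: Classification
    evidence: list = field(default_factory=list)  # list[ConceptMention]

    def __post_init__(self) -> None:
        if not self.lvsf_assessed and self.ef is not None:
            raise ValueError(
                f"patient {self.patient_id}: EF value without LVSF assessed"
            )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "lvsf_assessed": self.lvsf_assessed,
            "ef": self.ef.to_dict() if self.ef else None,
            "ef_lt_40": self.ef_lt_40,
            "on_acei_arb": self.on_acei_arb,
            "rnm_present": self.rnm_present,
            "classification": self.classification.value,
            "evidence": [m.to_dict() for m in self.evidence],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientDeterminations":
        return cls(
            patient_id=d["patient_id"],
            lvsf_assessed=d["lvsf_assessed"],
            ef=EFValue.from_dict(d["ef"]) if d.get("ef") else None,
            ef_lt_40=d.get("ef_lt_40"),
            on_acei_arb=d["on_acei_arb"],
            rnm_present=d["rnm_present"],
            classification=Classification(d["classification"]),
            evidence=[ConceptMention.from_dict(m) for m in d.get("evidence", [])],
        )


@dataclass
class GoldAnnotation:
    """Reference-standard truth for one patient: concept mentions plus the
    patient-level determination."""

    patient_id: str
    mentions: list = field(default_factory=list)  # list[ConceptMention]
    determination: Optional[PatientDeterminations] = None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mentions": [m.to_dict() for m in self.mentions],
            "determination": self.determination.to_dict()
            if self.determination
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GoldAnnotation":
        return cls(
            patient_id=d["patient_id"],
            mentions=[ConceptMention.from_dict(m) for m in d.get("mentions", [])],
            determination=PatientDeterminations.from_dict(d["determination"])
            if d.get("determination")
            else None,
        )


class Corpus:
    """An in-memory note collection with per-patient grouping.

    Iterating yields notes in insertion order; ``by_patient`` groups them,
    preserving first-seen patient order.
    """

    def __init__(self, notes: Iterable[ClinicalNote] = ()):
        self.notes: list[ClinicalNote] = []
        self._ids: set[str] = set()
        for note in notes:
            self.add(note)

    def add(self, note: ClinicalNote) -> None:
        if note.note_id in self._ids:
            raise ValueError(f"duplicate note_id: {note.note_id}")
        self._ids.add(note.note_id)
        self.notes.append(note)

    def __iter__(self) -> Iterator[ClinicalNote]:
        return iter(self.notes)

    def __len__(self) -> int:
        return len(self.notes)

    def by_patient(self) -> dict[str, list[ClinicalNote]]:
        groups: dict[str, list[ClinicalNote]] = {}
        for note in self.notes:
            groups.setdefault(note.patient_id, []).append(note)
        return groups

    def get_note(self, note_id: str) -> ClinicalNote:
        for note in self.notes:
            if note.note_id == note_id:
                return note
        raise KeyError(note_id)


__all__ = [
    "Classification",
    "ClinicalNote",
    "Concept",
    "ConceptMention",
    "Corpus",
    "DocType",
    "DrugClass",
    "EFValue",
    "GoldAnnotation",
    "MedMatch",
    "PatientDeterminations",
    "QualitativeEF",
    "RNMCategory",
    "SectionLabel",
    "SectionSpan",
    "SentenceSpan",
    "replace",
]
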