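"""Patient-level roll-up and CHI19 classification.

Document-level mentions are rolled up with the document-preference rules a
human abstractor uses: the most recent echocardiogram (narrative summary
section first) for the EF, and the discharge medication reconciliation form
(then the discharge summary, then any document) for ACEI/ARB status.  The
rolled-up facts then pass through the measure algorithm:

    MET  iff  (LVSF assessed and EF not <40%)
          or  (EF <40% and on ACEI/ARB)
          or  (EF <40%, not on ACEI/ARB, and a reason-no-medication documented)

Everything else — including patients with no EF documented at all, and
patients whose only EF statement leaves the <40% question open — is NOT_MET.
The algorithm is total: every patient receives a label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .extraction import (
    MedLexicon,
    RNMTrigger,
    assert_context_all,
    default_lexicon,
    extract_ef_mentions,
    extract_med_mentions,
    extract_rnm_mentions,
)
from .preprocess import segment_sections, split_sentences
from .types import (
    Classification,
    ClinicalNote,
    Concept,
    ConceptMention,
    Corpus,
    DocType,
    EFValue,
    PatientDeterminations,
    SectionLabel,
)

log = logging.getLogger(__name__)


@dataclass
class ClassificationConfig:
    """Knobs of the measure logic.

    ``strict_lt`` keeps the threshold strict: an EF of exactly 40% is "not
    <40%" and meets the measure on the assessed branch.  ``count_unvalued_ef``
    controls whether an EF mention without a resolvable value still counts as
    "LVSF assessed" (it never counts toward EF <40%).
    """

    ef_threshold: float = 40.0
    prefer_echo_for_ef: bool = True
    prefer_med_recon_for_meds: bool = True
    strict_lt: bool = True
    count_unvalued_ef: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ef_threshold < 100:
            raise ValueError("ef_threshold must be in (0, 100)")


NotePair = tuple[ClinicalNote, ConceptMention]


def _doc_key(note: ClinicalNote) -> tuple:
    return note.sort_key


def select_ef_for_patient(
    pairs: Sequence[NotePair],
    config: Optional[ClassificationConfig] = None,
) -> tuple[bool, Optional[EFValue], Optional[bool], list[ConceptMention]]:
    """Choose the patient's EF from all EF mentions across their notes.

    Preference: (1) the most recent echocardiogram carrying an EF value,
    within it the narrative-summary section; (2) the most recent document of
    any type carrying an EF value.  Within the chosen document, numeric
    values beat qualitative ones at equal section preference, and ties go to
    the last mention in document order.

    Returns ``(lvsf_assessed, chosen EF or None, ef_lt_40, evidence)`` where
    ``ef_lt_40`` is None when no value settles the question.
    """
    config = config or ClassificationConfig()
    ef_pairs = [(n, m) for n, m in pairs if m.concept is Concept.EF_MENTION]
    lvsf_assessed = any(
        m.value is not None or config.count_unvalued_ef for _, m in ef_pairs
    ) and bool(ef_pairs)

    valued = [(n, m) for n, m in ef_pairs if isinstance(m.value, EFValue)]
    if not valued:
        return lvsf_assessed, None, None, [m for _, m in ef_pairs[:1]]

    echo_notes = {
        n.note_id: n
        for n, _ in valued
        if n.doc_type is DocType.ECHOCARDIOGRAM
    }
    if config.prefer_echo_for_ef and echo_notes:
        chosen_note = max(echo_notes.values(), key=_doc_key)
    else:
        chosen_note = max({n.note_id: n for n, _ in valued}.values(), key=_doc_key)

    in_doc = [m for n, m in valued if n.note_id == chosen_note.note_id]

    def rank(m: ConceptMention) -> tuple:
        in_summary = (
            chosen_note.doc_type is DocType.ECHOCARDIOGRAM
            and m.section is SectionLabel.ECHO_NARRATIVE_SUMMARY
        )
        numeric = m.value.form != "qualitative"
        return (in_summary, numeric, m.start)

    best = max(in_doc, key=rank)
    ef: EFValue = best.value
    ef_lt = ef.is_below(config.ef_threshold, strict=config.strict_lt)
    return lvsf_assessed, ef, ef_lt, [best]


def determine_discharge_meds(
    pairs: Sequence[NotePair],
    config: Optional[ClassificationConfig] = None,
) -> tuple[bool, list[ConceptMention]]:
    """Decide ACEI/ARB-at-discharge status from medication mentions.

    The preferred source is the first tier containing any ACEI/ARB mention:
    (1) the most recent pharmacy medication-reconciliation document, (2) the
    discharge summary, (3) any document.  Within that source the patient is
    on an ACEI/ARB iff at least one mention is neither negated nor
    discontinued — so a lone "lisinopril discontinued" in the reconciliation
    form means *not* on therapy even if an old progress note says otherwise.
    """
    config = config or ClassificationConfig()
    med_pairs = [(n, m) for n, m in pairs if m.concept is Concept.ACEI_ARB]
    if not med_pairs:
        return False, []

    tiers: list[list[NotePair]] = []
    if config.prefer_med_recon_for_meds:
        tiers.append(
            [(n, m) for n, m in med_pairs if n.doc_type is DocType.PHARMACY_MED_RECON]
        )
        tiers.append(
            [(n, m) for n, m in med_pairs if n.doc_type is DocType.DISCHARGE_SUMMARY]
        )
    tiers.append(list(med_pairs))

    for tier in tiers:
        if not tier:
            continue
        newest = max({n.note_id: n for n, _ in tier}.values(), key=_doc_key)
        evidence = [m for n, m in tier if n.note_id == newest.note_id]
        active = [m for m in evidence if not m.negated and not m.discontinued]
        return bool(active), evidence
    return False, []  # pragma: no cover - last tier is non-empty by guard


def determine_rnm(
    pairs: Sequence[NotePair],
) -> tuple[bool, list[ConceptMention]]:
    """A reason-no-medication holds iff any non-negated RNM mention exists."""
    rnm = [m for _, m in pairs if m.concept is Concept.RNM]
    positive = [m for m in rnm if not m.negated]
    return bool(positive), positive


def classify(
    lvsf_assessed: bool,
    ef_lt_40: Optional[bool],
    on_acei_arb: bool,
    rnm_present: bool,
) -> Classification:
    """The measure's boolean core, total over all inputs.

    ``ef_lt_40=None`` (no value, or an indeterminate one) satisfies neither
    the "not <40%" branch nor the "<40%" branches, so such patients are
    NOT_MET unless nothing else applies — mirroring a conservative abstractor.
    """
    met = (
        (lvsf_assessed and ef_lt_40 is False)
        or (ef_lt_40 is True and on_acei_arb)
        or (ef_lt_40 is True and not on_acei_arb and rnm_present)
    )
    return Classification.MET if met else Classification.NOT_MET


def classify_patient(
    determinations: PatientDeterminations,
    config: Optional[ClassificationConfig] = None,
) -> Classification:
    """Apply the measure algorithm to rolled-up patient facts."""
    return classify(
        determinations.lvsf_assessed,
        determinations.ef_lt_40,
        determinations.on_acei_arb,
        determinations.rnm_present,
    )


@dataclass
class PipelineComponents:
    """Pluggable resources for a pipeline run."""

    lexicon: MedLexicon = field(default_factory=default_lexicon)
    rnm_triggers: Optional[list[RNMTrigger]] = None
    header_table: Optional[list] = None


def process_patient(
    patient_id: str,
    notes: Sequence[ClinicalNote],
    config: Optional[ClassificationConfig] = None,
    components: Optional[PipelineComponents] = None,
) -> PatientDeterminations:
    """Extract, assert context, roll up, and classify one patient."""
    config = config or ClassificationConfig()
    components = components or PipelineComponents()
    pairs: list[NotePair] = []
    for note in notes:
        try:
            sections = segment_sections(note.text, note.doc_type, components.header_table)
            sentences = split_sentences(note.text)
            mentions = extract_ef_mentions(note, sections)
            mentions += extract_med_mentions(note, components.lexicon, sections)
            mentions += extract_rnm_mentions(
                note, components.rnm_triggers, components.lexicon, sections, sentences
            )
            assert_context_all(mentions, note.text, sentences)
            pairs.extend((note, m) for m in mentions)
        except Exception:
            log.warning(
                "skipping note %s of patient %s after extraction error",
                note.note_id,
                patient_id,
                exc_info=True,
            )
    lvsf_assessed, ef, ef_lt, ef_evidence = select_ef_for_patient(pairs, config)
    on_med, med_evidence = determine_discharge_meds(pairs, config)
    rnm_present, rnm_evidence = determine_rnm(pairs)
    label = classify(lvsf_assessed, ef_lt, on_med, rnm_present)
    return PatientDeterminations(
        patient_id=patient_id,
        lvsf_assessed=lvsf_assessed,
        ef=ef,
        ef_lt_40=ef_lt,
        on_acei_arb=on_med,
        rnm_present=rnm_present,
        classification=label,
        evidence=ef_evidence + med_evidence + rnm_evidence,
    )


def run_pipeline(
    corpus: Corpus | Iterable[ClinicalNote],
    config: Optional[ClassificationConfig] = None,
    components: Optional[PipelineComponents] = None,
) -> list[PatientDeterminations]:
    """Run the full pipeline; exactly one determination per patient.

    A malformed note is skipped with a warning; the patient is still
    classified from their remaining notes, so classification coverage is
    always 100%.
    """
    if not isinstance(corpus, Corpus):
        corpus = Corpus(corpus)
    components = components or PipelineComponents()
    return [
        process_patient(pid, notes, config, components)
        for pid, notes in corpus.by_patient().items()
    ]


__all__ = [
    "ClassificationConfig",
    "PipelineComponents",
    "classify",
    "classify_patient",
    "determine_discharge_meds",
    "determine_rnm",
    "process_patient",
    "run_pipeline",
    "select_ef_for_patient",
]
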