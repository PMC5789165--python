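"""Synthetic clinical-note corpus generator with planted gold annotations.

The generator emulates the structure of a VA-style inpatient heart-failure
corpus so the whole pipeline — preprocessing, extraction, roll-up,
classification, evaluation — runs end to end with no clinical data:

* ten document types per discharge (history & physical, echocardiogram,
  pharmacy medication reconciliation, discharge summary, progress/nursing/
  consult/pharmacy/other filler notes);
* EF statements concentrated in the echocardiogram narrative summary and
  assessment / current-history sections, medications in medication and
  assessment sections, reasons-no-medication in assessment sections;
* a latent truth per patient (EF documented? value? on ACEI/ARB? RNM?) from
  which both the note text and the gold annotations are derived, with the
  patient-level gold classification computed by the same measure formula
  the classifier uses.

Canonical renderings are exactly invertible by the extractors (rendered
span == extracted span, value round-trips), so on a noise-free corpus the
pipeline reproduces gold with sensitivity = PPV = 100%.  Setting
``variant_noise_rate`` > 0 renders that fraction of concepts in surface
forms outside the extractor's pattern set; the noise decisions are drawn
from a dedicated RNG stream in a fixed order, so the set of noise-rendered
concepts is nested as the rate grows at a fixed seed and pipeline
sensitivity degrades monotonically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify
from .extraction import default_lexicon
from .io import write_corpus, write_gold
from .preprocess import map_document_type
from .types import (
    Classification,
    ClinicalNote,
    Concept,
    ConceptMention,
    Corpus,
    DocType,
    DrugClass,
    EFValue,
    GoldAnnotation,
    MedMatch,
    PatientDeterminations,
    QualitativeEF,
    RNMCategory,
    SectionLabel,
)

# --- corpus specification --------------------------------------------------


@dataclass
class CorpusSpec:
    """Generator configuration.

    The latent-truth probabilities are chosen so that every branch of the
    measure algorithm is well populated at a few hundred patients; the RNM
    prevalence default follows the ~14.9% contraindication rate reported in
    the heart-failure literature.  ``p_rnm_given_lt40_no_med`` fixes the RNM
    rate inside the branch where RNM decides the classification; the rate
    elsewhere is solved so the overall prevalence hits
    ``p_rnm_overall_target`` in expectation.
    """

    n_patients: int = 500
    seed: int = 0
    p_ef_documented: float = 0.93
    p_ef_lt40_given_documented: float = 0.5
    p_on_med_given_lt40: float = 0.85
    p_rnm_given_lt40_no_med: float = 0.5
    p_rnm_overall_target: float = 0.149
    p_on_med_otherwise: float = 0.25  # ACEIs are common antihypertensives
    notes_per_patient: tuple[int, int] = (3, 8)
    doc_type_mix: dict = field(
        default_factory=lambda: {
            DocType.PROGRESS_NOTE: 0.40,
            DocType.NURSING_NOTE: 0.25,
            DocType.CARDIOLOGY_CONSULT: 0.10,
            DocType.CONSULT_OTHER: 0.10,
            DocType.PHARMACY_OTHER: 0.05,
            DocType.OTHER_GENERAL: 0.10,
        }
    )
    variant_noise_rate: float = 0.0
    start_date: datetime = field(default_factory=lambda: datetime(2008, 1, 1, 8, 0))

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in (
            "p_ef_documented",
            "p_ef_lt40_given_documented",
            "p_on_med_given_lt40",
            "p_rnm_given_lt40_no_med",
            "p_rnm_overall_target",
            "p_on_med_otherwise",
            "variant_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.notes_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("notes_per_patient must satisfy 1 <= lo <= hi")

    @property
    def p_rnm_elsewhere(self) -> float:
        """RNM rate outside the EF<40-and-no-med branch, solved so the
        overall prevalence matches ``p_rnm_overall_target`` in expectation."""
        p_branch = (
            self.p_ef_documented
            * self.p_ef_lt40_given_documented
            * (1.0 - self.p_on_med_given_lt40)
        )
        if p_branch >= 1.0:
            return 0.0
        p = (self.p_rnm_overall_target - p_branch * self.p_rnm_given_lt40_no_med) / (
            1.0 - p_branch
        )
        return float(min(1.0, max(0.0, p)))

    @property
    def expected_met_rate(self) -> float:
        """Spec-implied P(measure met) under the latent-truth model."""
        d = self.p_ef_documented
        q = self.p_ef_lt40_given_documented
        m = self.p_on_med_given_lt40
        r = self.p_rnm_given_lt40_no_med
        return d * (1 - q) + d * q * m + d * q * (1 - m) * r

    @classmethod
    def va_prevalence(cls, **overrides) -> "CorpusSpec":
        """Prevalence preset resembling VA inpatient HF cohorts, where ~92%
        of classifiable discharges meet the measure."""
        defaults = dict(
            p_ef_documented=0.95,
            p_ef_lt40_given_documented=0.40,
            p_on_med_given_lt40=0.85,
            p_rnm_given_lt40_no_med=0.40,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def heavy(cls, **overrides) -> "CorpusSpec":
        """Document density close to a real discharge bundle (tens of notes
        per patient) — slower, for load-style runs."""
        defaults = dict(notes_per_patient=(30, 50))
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "p_ef_documented": self.p_ef_documented,
            "p_ef_lt40_given_documented": self.p_ef_lt40_given_documented,
            "p_on_med_given_lt40": self.p_on_med_given_lt40,
            "p_rnm_given_lt40_no_med": self.p_rnm_given_lt40_no_med,
            "p_rnm_overall_target": self.p_rnm_overall_target,
            "p_on_med_otherwise": self.p_on_med_otherwise,
            "notes_per_patient": list(self.notes_per_patient),
            "doc_type_mix": {k.value: v for k, v in self.doc_type_mix.items()},
            "variant_noise_rate": self.variant_noise_rate,
            "start_date": self.start_date.isoformat(),
        }


# --- canonical rendering templates ----------------------------------------

EF_POINT_TEMPLATES = [
    "LVEF {v}%",
    "EF {v}%",
    "EF is {v}%",
    "Ejection fraction of {v}%",
    "LV EF {v}%",
]
EF_RANGE_TEMPLATES = [
    "EF {lo}-{hi}%",
    "LVEF {lo}-{hi}%",
    "EF {lo} to {hi}%",
]
EF_QUALITATIVE_TEMPLATES = {
    QualitativeEF.SEVERELY_REDUCED: [
        "severely reduced systolic function",
        "left ventricular systolic function is severely reduced",
        "LVEF severely reduced",
    ],
    QualitativeEF.MODERATELY_REDUCED: [
        "moderately reduced systolic function",
        "left ventricular systolic function is moderately reduced",
        "LVEF moderately reduced",
    ],
    QualitativeEF.NORMAL_OR_PRESERVED: [
        "normal systolic function",
        "preserved ejection fraction",
        "LVEF is normal",
    ],
}


def _fmt(v: float) -> str:
    return f"{v:g}"


def render_ef(value: EFValue, template_id: int = 0) -> str:
    """Render an EF value with a canonical template.

    Canonical renderings are invertible: ``parse_ef_value(render_ef(v)) == v``
    for every template, and the rendered snippet equals the span the
    extractor reports.
    """
    if value.form == "point":
        t = EF_POINT_TEMPLATES[template_id % len(EF_POINT_TEMPLATES)]
        return t.format(v=_fmt(value.low))
    if value.form == "range":
        t = EF_RANGE_TEMPLATES[template_id % len(EF_RANGE_TEMPLATES)]
        return t.format(lo=_fmt(value.low), hi=_fmt(value.high))
    templates = EF_QUALITATIVE_TEMPLATES[value.qualitative_label]
    return templates[template_id % len(templates)]


def render_ef_noise(value: EFValue, template_id: int = 0) -> str:
    """An out-of-template rendering the extractor deliberately cannot parse."""
    if value.form == "qualitative":
        return "pump function looks weak on imaging"
    return f"visually estimated pump strength {_fmt(value.representative)} percent"


# RNM templates: (category, sentence, reason-phrase substring, med substring,
# med flags).  The reason substring and med substring locate the gold spans.
_RNM_TEMPLATES: list[tuple[RNMCategory, str, str, Optional[str], dict]] = [
    (
        RNMCategory.HYPERKALEMIA,
        "ACEI contraindicated due to hyperkalemia.",
        "hyperkalemia",
        "ACEI",
        {"discontinued": True},
    ),
    (
        RNMCategory.RENAL_DYSFUNCTION,
        "Lisinopril held due to worsening renal function.",
        "worsening renal function",
        "Lisinopril",
        {"discontinued": True},
    ),
    (
        RNMCategory.ANGIOEDEMA,
        "ARB stopped due to angioedema.",
        "angioedema",
        "ARB",
        {"discontinued": True},
    ),
    (
        RNMCategory.HYPOTENSION,
        "ACE inhibitor held due to hypotension.",
        "hypotension",
        "ACE inhibitor",
        {"discontinued": True},
    ),
    (
        RNMCategory.PATIENT_REFUSAL,
        "Patient refused ACEI therapy.",
        "refused",
        "ACEI",
        {"discontinued": True},
    ),
    (
        RNMCategory.COMFORT_CARE,
        "ACEI held; patient transitioned to comfort care.",
        "comfort care",
        "ACEI",
        {"discontinued": True},
    ),
    (
        RNMCategory.ALLERGY_INTOLERANCE,
        "Allergy to lisinopril documented.",
        "Allergy",
        "lisinopril",
        {"discontinued": True},
    ),
]

_RNM_NOISE_SENTENCE = "Renin-angiotensin blockade deferred at this time."

_FILLER_SENTENCES = [
    "Patient resting in bed, vital signs stable.",
    "Ambulated in hallway with assistance.",
    "Diet advanced as ordered.",
    "Telemetry reviewed overnight, no events.",
    "Lungs clear to auscultation bilaterally.",
    "Plan to follow up with primary care in two weeks.",
    "Daily weights and strict intake and output continue.",
    "Family at bedside, questions answered.",
]

_DISTRACTOR_MEDS = [
    "Furosemide 40 mg PO daily",
    "Metoprolol succinate 25 mg PO daily",
    "Atorvastatin 40 mg PO nightly",
    "Aspirin 81 mg PO daily",
    "Spironolactone 25 mg PO daily",
]


class _NoteBuilder:
    """Accumulates note text while registering gold mention spans."""

    def __init__(self, note_id: str):
        self.note_id = note_id
        self.parts: list[str] = []
        self.pos = 0
        self.mentions: list[ConceptMention] = []

    def write(self, text: str) -> int:
        start = self.pos
        self.parts.append(text)
        self.pos += len(text)
        return start

    def mention(
        self,
        concept: Concept,
        start: int,
        length: int,
        value,
        section: SectionLabel,
        **flags,
    ) -> None:
        self.mentions.append(
            ConceptMention(
                concept=concept,
                note_id=self.note_id,
                start=start,
                end=start + length,
                value=value,
                section=section,
                **flags,
            )
        )

    def text(self) -> str:
        return "".join(self.parts)


@dataclass
class _Latent:
    ef_documented: bool
    ef_lt40: bool
    ef: Optional[EFValue]
    on_med: bool
    rnm: bool
    drug: Optional[tuple[str, str, DrugClass]]  # (surface, generic, class)
    rnm_template: int


def _sample_ef(rng: np.random.Generator, lt40: bool) -> EFValue:
    form = rng.choice(["point", "range", "qualitative"], p=[0.6, 0.25, 0.15])
    if form == "point":
        v = int(rng.integers(15, 40)) if lt40 else int(rng.integers(41, 71))
        return EFValue.point(float(v))
    if form == "range":
        lo = int(rng.integers(15, 34)) if lt40 else int(rng.integers(45, 61))
        return EFValue.range(float(lo), float(lo + 5))
    if lt40:
        label = (
            QualitativeEF.SEVERELY_REDUCED
            if rng.random() < 0.5
            else QualitativeEF.MODERATELY_REDUCED
        )
    else:
        label = QualitativeEF.NORMAL_OR_PRESERVED
    return EFValue.qualitative(label)


def _sample_drug(rng: np.random.Generator) -> tuple[str, str, DrugClass]:
    lexicon = default_lexicon()
    entry = lexicon.entries[int(rng.integers(0, len(lexicon.entries)))]
    if entry.variants and rng.random() < 0.3:
        surface = entry.variants[int(rng.integers(0, len(entry.variants)))]
    else:
        surface = entry.generic
    return surface.capitalize(), entry.generic, entry.drug_class


def _sample_latent(spec: CorpusSpec, rng: np.random.Generator) -> _Latent:
    documented = rng.random() < spec.p_ef_documented
    lt40 = documented and rng.random() < spec.p_ef_lt40_given_documented
    ef = _sample_ef(rng, lt40) if documented else None
    if lt40:
        on_med = rng.random() < spec.p_on_med_given_lt40
    else:
        on_med = rng.random() < spec.p_on_med_otherwise
    in_branch = documented and lt40 and not on_med
    p_rnm = spec.p_rnm_given_lt40_no_med if in_branch else spec.p_rnm_elsewhere
    rnm = rng.random() < p_rnm
    drug = _sample_drug(rng) if on_med else None
    return _Latent(
        ef_documented=documented,
        ef_lt40=lt40,
        ef=ef,
        on_med=on_med,
        rnm=rnm,
        drug=drug,
        rnm_template=int(rng.integers(0, len(_RNM_TEMPLATES))),
    )


def _write_ef(
    builder: _NoteBuilder,
    ef: EFValue,
    section: SectionLabel,
    template_id: int,
    noisy: bool,
) -> None:
    snippet = (
        render_ef_noise(ef, template_id) if noisy else render_ef(ef, template_id)
    )
    start = builder.write(snippet)
    builder.mention(Concept.EF_MENTION, start, len(snippet), ef, section)


def _write_med(
    builder: _NoteBuilder,
    surface: str,
    generic: str,
    drug_class: DrugClass,
    section: SectionLabel,
    noisy: bool,
    **flags,
) -> None:
    rendered = surface[:-1] if noisy else surface  # noise: clipped surface form
    start = builder.write(rendered)
    builder.mention(
        Concept.ACEI_ARB,
        start,
        len(rendered),
        MedMatch(generic=generic, drug_class=drug_class),
        section,
        **flags,
    )


def _write_rnm_sentence(
    builder: _NoteBuilder,
    latent: _Latent,
    section: SectionLabel,
    noisy: bool,
    lexicon,
) -> None:
    category, sentence, reason_sub, med_sub, med_flags = _RNM_TEMPLATES[
        latent.rnm_template % len(_RNM_TEMPLATES)
    ]
    if noisy:
        start = builder.write(_RNM_NOISE_SENTENCE)
        builder.mention(
            Concept.RNM,
            start + _RNM_NOISE_SENTENCE.index("deferred"),
            len("deferred"),
            category,
            section,
        )
        return
    start = builder.write(sentence)
    r = sentence.index(reason_sub)
    builder.mention(Concept.RNM, start + r, len(reason_sub), category, section)
    if med_sub is not None:
        m = sentence.index(med_sub)
        match = lexicon.lookup(med_sub)
        builder.mention(
            Concept.ACEI_ARB,
            start + m,
            len(med_sub),
            match,
            section,
            **med_flags,
        )


def _filler(rng: np.random.Generator, k: int = 2) -> str:
    idx = rng.choice(len(_FILLER_SENTENCES), size=k, replace=False)
    return " ".join(_FILLER_SENTENCES[i] for i in idx)


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, list[GoldAnnotation]]:
    """Generate a corpus and its gold annotations.

    Deterministic: the same spec and seed yield byte-identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    child_struct, child_noise = ss.spawn(2)
    rng = np.random.default_rng(child_struct)
    noise_rng = np.random.default_rng(child_noise)
    lexicon = default_lexicon()

    def noisy() -> bool:
        # Draw unconditionally so noise decisions are nested across rates.
        return bool(noise_rng.random() < spec.variant_noise_rate)

    corpus = Corpus()
    gold: list[GoldAnnotation] = []
    mix_types = list(spec.doc_type_mix.keys())
    mix_p = np.array([spec.doc_type_mix[t] for t in mix_types], dtype=float)
    mix_p = mix_p / mix_p.sum()

    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        latent = _sample_latent(spec, rng)
        admit = spec.start_date + timedelta(
            days=int(rng.integers(0, 300)), hours=int(rng.integers(0, 10))
        )
        stay = int(rng.integers(3, 9))
        n_notes = int(rng.integers(spec.notes_per_patient[0], spec.notes_per_patient[1] + 1))

        mentions: list[ConceptMention] = []
        note_no = 0

        def new_builder() -> _NoteBuilder:
            nonlocal note_no
            note_no += 1
            return _NoteBuilder(f"{pid}-N{note_no:02d}")

        def finish(builder: _NoteBuilder, title: str, when: datetime) -> None:
            note = ClinicalNote(
                note_id=builder.note_id,
                patient_id=pid,
                note_datetime=when,
                title=title,
                text=builder.text(),
            )
            note.doc_type = map_document_type(title)
            corpus.add(note)
            mentions.extend(builder.mentions)

        # --- history & physical (admission day) ---
        b = new_builder()
        b.write("HPI:\n")
        b.write("Admitted with dyspnea and lower extremity edema. ")
        if latent.ef_documented and rng.random() < 0.5:
            _write_ef(
                b,
                latent.ef,
                SectionLabel.CURRENT_HISTORY,
                int(rng.integers(0, 5)),
                noisy(),
            )
            b.write(" per prior imaging. ")
        b.write(_filler(rng) + "\n")
        finish(b, "HISTORY AND PHYSICAL", admit)

        # --- echocardiogram (day 1) ---
        if latent.ef_documented:
            b = new_builder()
            b.write("FINDINGS:\n")
            b.write(
                "Left atrium mildly dilated. Aortic valve trileaflet without "
                "stenosis. No pericardial effusion.\n"
            )
            b.write("CONCLUSIONS:\n")
            _write_ef(
                b,
                latent.ef,
                SectionLabel.ECHO_NARRATIVE_SUMMARY,
                int(rng.integers(0, 5)),
                noisy(),
            )
            b.write(". Diastolic parameters within normal limits for age.\n")
            finish(b, "ECHOCARDIOGRAM REPORT", admit + timedelta(days=1, hours=2))

        # --- progress note with assessment (mid-stay) ---
        b = new_builder()
        b.write("ASSESSMENT:\n")
        b.write("Acute on chronic heart failure, improving on diuresis. ")
        if latent.ef_documented and rng.random() < 0.4:
            _write_ef(
                b, latent.ef, SectionLabel.ASSESSMENT, int(rng.integers(0, 5)), noisy()
            )
            b.write(". ")
        if latent.on_med and rng.random() < 0.5:
            b.write("Continue ")
            _write_med(
                b,
                latent.drug[0],
                latent.drug[1],
                latent.drug[2],
                SectionLabel.ASSESSMENT,
                noisy(),
            )
            b.write(" at current dose. ")
        elif not latent.on_med and not latent.rnm and rng.random() < 0.5:
            b.write("Not on ")
            _write_med(
                b,
                "ACE inhibitor",
                None,
                DrugClass.ACEI,
                SectionLabel.ASSESSMENT,
                noisy(),
                negated=True,
            )
            b.write(" currently. ")
        b.write(_filler(rng, 1) + "\n")
        finish(
            b,
            "PROGRESS NOTE",
            admit + timedelta(days=max(1, stay // 2), hours=1),
        )

        # --- pharmacy medication reconciliation (discharge day) ---
        b = new_builder()
        b.write("DISCHARGE MEDICATIONS:\n")
        n_distract = int(rng.integers(2, 5))
        order = rng.permutation(len(_DISTRACTOR_MEDS))[:n_distract]
        listed = [_DISTRACTOR_MEDS[j] for j in sorted(order)]
        insert_at = int(rng.integers(0, n_distract + 1)) if latent.on_med else -1
        for j, line in enumerate(listed):
            if j == insert_at:
                _write_med(
                    b,
                    latent.drug[0],
                    latent.drug[1],
                    latent.drug[2],
                    SectionLabel.MEDICATIONS,
                    noisy(),
                )
                b.write(" 10 mg PO daily\n")
            b.write(line + "\n")
        if insert_at == n_distract:
            _write_med(
                b,
                latent.drug[0],
                latent.drug[1],
                latent.drug[2],
                SectionLabel.MEDICATIONS,
                noisy(),
            )
            b.write(" 10 mg PO daily\n")
        finish(
            b,
            "PHARMACY MEDICATION RECONCILIATION",
            admit + timedelta(days=stay, hours=3),
        )

        # --- discharge summary (discharge day) ---
        b = new_builder()
        b.write("HOSPITAL COURSE:\n")
        b.write("Diuresed with improvement in symptoms. ")
        if latent.ef_documented and rng.random() < 0.4:
            _write_ef(
                b, latent.ef, SectionLabel.ASSESSMENT, int(rng.integers(0, 5)), noisy()
            )
            b.write(" on echocardiogram this admission. ")
        if latent.on_med:
            b.write("Continue ")
            _write_med(
                b,
                latent.drug[0],
                latent.drug[1],
                latent.drug[2],
                SectionLabel.ASSESSMENT,
                noisy(),
            )
            b.write(" at discharge. ")
        if latent.rnm:
            _write_rnm_sentence(b, latent, SectionLabel.ASSESSMENT, noisy(), lexicon)
            b.write(" ")
        b.write(_filler(rng, 1) + "\n")
        finish(b, "DISCHARGE SUMMARY", admit + timedelta(days=stay, hours=5))

        # --- concept-free filler notes ---
        n_filler = max(0, n_notes - note_no)
        titles = {
            DocType.PROGRESS_NOTE: "PROGRESS NOTE",
            DocType.NURSING_NOTE: "NURSING NOTE",
            DocType.CARDIOLOGY_CONSULT: "CARDIOLOGY CONSULT NOTE",
            DocType.CONSULT_OTHER: "DIETARY CONSULT",
            DocType.PHARMACY_OTHER: "PHARMACY NOTE",
            DocType.OTHER_GENERAL: "TELEPHONE ENCOUNTER",
        }
        for _ in range(n_filler):
            t = mix_types[int(rng.choice(len(mix_types), p=mix_p))]
            b = new_builder()
            b.write(_filler(rng, 3) + "\n")
            finish(
                b,
                titles[t],
                admit + timedelta(days=int(rng.integers(0, stay + 1)), hours=6),
            )

        # --- patient-level gold from latent truth ---
        ef_lt: Optional[bool] = latent.ef_lt40 if latent.ef_documented else None
        label = classify(latent.ef_documented, ef_lt, latent.on_med, latent.rnm)
        determination = PatientDeterminations(
            patient_id=pid,
            lvsf_assessed=latent.ef_documented,
            ef=latent.ef,
            ef_lt_40=ef_lt,
            on_acei_arb=latent.on_med,
            rnm_present=latent.rnm,
            classification=label,
        )
        gold.append(
            GoldAnnotation(patient_id=pid, mentions=mentions, determination=determination)
        )

    return corpus, gold


def corpus_summary(
    determinations: Sequence[PatientDeterminations] | Sequence[GoldAnnotation],
) -> pd.DataFrame:
    """Counts and percentages of patients by measure-met status."""
    labels = []
    for d in determinations:
        det = d.determination if isinstance(d, GoldAnnotation) else d
        if det is not None:
            labels.append(det.classification)
    total = len(labels)
    if total == 0:
        return pd.DataFrame(columns=["measure", "n", "percent"])
    met = sum(c is Classification.MET for c in labels)
    rows = [
        {"measure": "Met", "n": met, "percent": round(met / total * 100, 2)},
        {
            "measure": "Not met",
            "n": total - met,
            "percent": round((total - met) / total * 100, 2),
        },
        {"measure": "Total", "n": total, "percent": 100.0},
    ]
    return pd.DataFrame(rows)


def write_simulation(
    spec: CorpusSpec, out_dir: str | Path
) -> tuple[Corpus, list[GoldAnnotation]]:
    """Generate and write corpus + gold + a manifest with seed and hashes."""
    out_dir = Path(out_dir)
    corpus, gold = generate_corpus(spec)
    write_corpus(corpus, out_dir)
    write_gold(gold, out_dir / "gold.jsonl")
    digest = hashlib.sha256()
    for note in corpus:
        digest.update(note.note_id.encode())
        digest.update(note.text.encode())
    manifest = {
        "n_patients": len(corpus.by_patient()),
        "n_notes": len(corpus),
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "corpus_sha256": digest.hexdigest(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return corpus, gold


__all__ = [
    "CorpusSpec",
    "EF_POINT_TEMPLATES",
    "EF_QUALITATIVE_TEMPLATES",
    "EF_RANGE_TEMPLATES",
    "corpus_summary",
    "generate_corpus",
    "render_ef",
    "render_ef_noise",
    "write_simulation",
]
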