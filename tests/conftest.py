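from datetime import datetime, timedelta

import pytest

from hfquality.preprocess import map_document_type
from hfquality.types import ClinicalNote, Corpus

BASE = datetime(2008, 3, 1, 8, 0)


def make_note(
    note_id: str,
    text: str,
    title: str = "PROGRESS NOTE",
    patient_id: str = "P1",
    day: int = 0,
) -> ClinicalNote:
    note = ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        note_datetime=BASE + timedelta(days=day),
        title=title,
        text=text,
    )
    note.doc_type = map_document_type(title)
    return note


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two patients, three notes: one clearly-met patient (EF 25, on an
    ACEI per the med-recon form) and one with a normal EF."""
    return Corpus(
        [
            make_note(
                "n1",
                "FINDINGS:\nNo pericardial effusion.\nCONCLUSIONS:\nLVEF 25%. \n",
                title="ECHOCARDIOGRAM REPORT",
                patient_id="pa",
                day=1,
            ),
            make_note(
                "n2",
                "DISCHARGE MEDICATIONS:\nLisinopril 10 mg PO daily\nAspirin 81 mg PO daily\n",
                title="PHARMACY MEDICATION RECONCILIATION",
                patient_id="pa",
                day=4,
            ),
            make_note(
                "n3",
                "ASSESSMENT:\nEF 60%. Doing well.\n",
                title="PROGRESS NOTE",
                patient_id="pb",
                day=2,
            ),
        ]
    )
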