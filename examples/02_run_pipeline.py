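"""Classify a hand-written two-patient corpus.

Patient "pa" has a reduced EF (25%) on the echocardiogram and lisinopril on
the discharge medication reconciliation: the measure is MET via the
treated branch.  Patient "pb" has a reduced EF, no ACEI/ARB, and a
documented hyperkalemia contraindication: MET via the reason-no-medication
branch.
"""

from datetime import datetime

from hfquality import ClinicalNote, Corpus, map_document_type, run_pipeline


def note(note_id, patient_id, day, title, text):
    n = ClinicalNote(note_id, patient_id, datetime(2008, 3, day, 9, 0), title, text)
    n.doc_type = map_document_type(title)
    return n


corpus = Corpus(
    [
        note("a1", "pa", 2, "ECHOCARDIOGRAM REPORT",
             "CONCLUSIONS:\nLVEF 25%. Mild mitral regurgitation.\n"),
        note("a2", "pa", 5, "PHARMACY MEDICATION RECONCILIATION",
             "DISCHARGE MEDICATIONS:\nLisinopril 10 mg PO daily\nFurosemide 40 mg PO daily\n"),
        note("b1", "pb", 1, "ECHOCARDIOGRAM REPORT",
             "CONCLUSIONS:\nleft ventricular systolic function is severely reduced.\n"),
        note("b2", "pb", 6, "DISCHARGE SUMMARY",
             "HOSPITAL COURSE:\nACEI contraindicated due to hyperkalemia. "
             "Diuresed with good effect.\n"),
    ]
)

for det in run_pipeline(corpus):
    ef = det.ef.to_dict() if det.ef else None
    print(
        f"{det.patient_id}: LVSF assessed={det.lvsf_assessed}, "
        f"EF<40={det.ef_lt_40}, on ACEI/ARB={det.on_acei_arb}, "
        f"RNM={det.rnm_present} -> {det.classification.value}"
    )
    print(f"   chosen EF: {ef}")
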