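"""Generate a synthetic inpatient heart-failure note corpus with gold truth.

The generator samples a latent truth per patient (is the EF documented and
below 40%? is an ACEI/ARB on the discharge med list? is a reason-no-
medication documented?) and renders it into a realistic bundle of notes:
a history & physical, an echocardiogram report, progress notes, a pharmacy
medication reconciliation, and a discharge summary.
"""

from hfquality import CorpusSpec, corpus_summary, generate_corpus

spec = CorpusSpec(n_patients=200, seed=42)
corpus, gold = generate_corpus(spec)

print(f"patients: {len(gold)}, notes: {len(corpus)}")
print(f"expected measure-met rate under this spec: {spec.expected_met_rate:.3f}")
print()
print("Gold measure-met breakdown (percent of patients):")
print(corpus_summary(gold).to_string(index=False))
print()
note = corpus.notes[1]
print(f"--- sample note: {note.title} ({note.doc_type.value}) ---")
print(note.text)
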