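# hfquality

Automated measurement of the CHI19 inpatient heart-failure quality measure
from free-text clinical notes, with a full evaluation harness and a
synthetic note-corpus generator.

## The problem

Guideline-concordant care for heart failure with reduced ejection fraction
requires that the left ventricular ejection fraction (LVEF) be documented
and, when LVEF < 40%, that an ACEI or ARB be prescribed at discharge unless
a contraindication or other reason not to prescribe is documented.  Quality
programs encode this as the CHI19 measure and traditionally determine it by
manual chart abstraction, because the deciding facts — EF values,
medication lists, reasons not to prescribe — live mostly in free text.

`hfquality` automates that determination.  For each patient's note bundle
it:

1. **preprocesses** the text (document-type mapping over ten standard
   inpatient note types, abbreviation-safe sentence splitting, section
   segmentation via an editable header table);
2. **extracts** three concept families with deterministic lexicon/pattern/
   context rules: EF mentions with normalized values (points, ranges →
   midpoint, comparative bounds with direction, qualitative severity
   phrases), ACEI/ARB mentions normalized to generic name + class, and
   reasons-no-medication (RNM) in eight categories, with NegEx-style
   negation/discontinuation assertion;
3. **rolls up** to the patient level with the document-preference rules a
   human abstractor uses — the most recent echocardiogram (narrative
   summary section first) for the EF, the discharge medication
   reconciliation form (then discharge summary, then any note) for
   medications;
4. **classifies** each patient:

   MET ⇔ (LVEF documented ∧ LVEF ≥ 40%)
       ∨ (LVEF < 40% ∧ ACEI/ARB at discharge)
       ∨ (LVEF < 40% ∧ no ACEI/ARB ∧ RNM documented)

   Everyone else is NOT_MET; the algorithm is total, so 100% of patients
   receive a label.

The evaluation harness provides sensitivity / specificity / PPV as
percentages with exact (Clopper-Pearson) 95% binomial confidence intervals,
the F-measure `F = 2·SN·PPV/(SN+PPV)`, Cohen's kappa for concordance with
structured-data label vectors, inter-annotator percent agreement, and a
five-row patient-level report (measure met; LVSF assessed; EF < 40%;
ACEI/ARB; RNM).

Because real clinical corpora are restricted, the package ships a
first-class synthetic corpus generator: it samples a latent truth per
patient, renders it into a realistic note bundle (H&P, echocardiogram,
progress notes, pharmacy medication reconciliation, discharge summary,
fillers), and emits gold annotations at both the mention and patient level.
Canonical renderings are exactly invertible by the extractors, so the
pipeline's correctness is testable end to end.

## Worked example

```python
from hfquality import CorpusSpec, evaluate_run, generate_corpus, run_pipeline

corpus, gold = generate_corpus(CorpusSpec(n_patients=300, seed=7))
report = evaluate_run(run_pipeline(corpus), gold)
print(report.to_text())
```

prints

```
Patient-level evaluation (n=300)
Classification              SN % (95% CI)           PPV % (95% CI)               F
Measure met                 100.0 (98.7, 100.0)     100.0 (98.7, 100.0)      100.0
LVSF assessed               100.0 (98.7, 100.0)     100.0 (98.7, 100.0)      100.0
EF <40%                     100.0 (97.6, 100.0)     100.0 (97.6, 100.0)      100.0
ACEI or ARB                 100.0 (98.0, 100.0)     100.0 (98.0, 100.0)      100.0
Reason not on medications   100.0 (92.6, 100.0)     100.0 (92.6, 100.0)      100.0
```

On a noise-free synthetic corpus the pipeline reproduces the gold
classifications exactly — every sensitivity and PPV is 100% and the CIs are
the exact binomial intervals at each row's denominator.  Setting
`variant_noise_rate=0.4` in the spec renders 40% of concepts in surface
forms outside the extractor's patterns; sensitivity then falls (e.g. 72.5%
for measure-met at seed 7) while PPV stays at 100%, because missing
evidence can only demote a MET patient to NOT_MET, never invent a MET.

More narrative examples live in `examples/` (corpus simulation, a
hand-written two-patient classification, evaluation under noise, and the
evaluation statistics on published-style counts).

## Command line

```bash
hfquality simulate --n 500 --seed 7 --out corpus/
hfquality run corpus/ --out results.jsonl
hfquality evaluate results.jsonl corpus/gold.jsonl --out report.json
hfquality concordance pipeline_labels.txt pharmacy_labels.txt
```

Exit codes: 0 success, 2 input error, 3 internal invariant violation.
Lexicon, RNM-trigger, and section-header tables are plain TSV files shipped
in `src/hfquality/data/` and can be replaced via `--lexicon`,
`--rnm-triggers`, and `--headers`.

## Layout

- `src/hfquality/types.py` — domain types (notes, mentions, EF values,
  patient determinations, gold annotations)
- `src/hfquality/io.py` — corpus directory, JSON-lines results/gold,
  BRAT-style standoff import
- `src/hfquality/preprocess.py` — document-type mapping, sentences,
  tokens, sections
- `src/hfquality/extraction.py` — EF / medication / RNM extractors and
  context assertion
- `src/hfquality/classify.py` — document-preference roll-up and the
  measure algorithm
- `src/hfquality/metrics.py` — evaluation statistics and the report
- `src/hfquality/simulate.py` — synthetic corpus generator
- `src/hfquality/cli.py` — thin command-line interface
- `docs/methods.md` — models, parameters, numerical choices, limitations
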