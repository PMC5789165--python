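# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## The measure algorithm

The unit of analysis is one patient discharge, represented as a bundle of
free-text notes.  Four patient-level facts are established from text:

- `lvsf_assessed` — any EF mention exists (an EF in the record is taken as
  evidence that left ventricular systolic function was assessed);
- `ef_lt_40` — whether the chosen EF establishes a value strictly below
  40%: `True`, `False`, or indeterminate (`None`);
- `on_acei_arb` — an active ACEI/ARB in the preferred medication source;
- `rnm_present` — a non-negated documented reason not to prescribe.

Classification is the three-branch disjunction given in the README.  Two
deliberate conservatisms:

- **No-EF and indeterminate-EF patients are NOT_MET.** The measure's met
  conditions all require an EF verdict; a patient whose only EF statement
  is "mildly reduced" (or a comparative bound straddling 40%, e.g.
  "EF > 30%") has LVSF assessed but no <40% verdict, and none of the met
  branches fire.  The `lvsf_assessed` flag is reported separately so the
  assessment signal is not lost.
- **EF exactly 40 is "not <40%"** under the default `strict_lt=True`,
  matching the measure's strict threshold.  The flag exists because
  secondary sources sometimes paraphrase the threshold as "≤"; flipping it
  moves EF=40 patients to the reduced-EF branches.

### Document preference

Human abstractors do not treat all notes equally, and neither does the
roll-up:

- **EF**: most recent echocardiogram document carrying an EF value, and
  within it the narrative-summary section (the reviewing cardiologist's
  conclusion), is preferred over any other note; otherwise the most recent
  document with a value.  Within a document, numeric beats qualitative and
  later beats earlier.  Undated notes sort before all dated notes (logged),
  so they lose "most recent" contests.
- **Medications**: the first non-empty tier among (1) the most recent
  pharmacy medication-reconciliation document, (2) the discharge summary,
  (3) any document decides; within it, the patient is on therapy iff at
  least one mention is neither negated nor discontinued.  A reconciliation
  form that records a stop therefore overrides an older "continue" note.
- **RNM**: any non-negated reason mention in any document suffices.

## Extraction

The extractors are deterministic lexicon/pattern/context rules with three
editable TSV resources (medication lexicon, RNM triggers, section headers).
This is a deliberate design: rule extractors are inspectable, exactly
reproducible, and sufficient to exercise every downstream computation;
sites with different note dialects extend the tables rather than retrain a
model.

- **EF values.** Triggers are "EF", "LVEF", "ejection fraction", and
  "(left ventricular) systolic function".  A value is searched within 60
  characters after the trigger, stopping at sentence boundaries: ranges
  first ("30-35%" → midpoint 32.5), then comparatives ("> 55%" keeps its
  direction, so it can never satisfy <40% while "< 20%" always does), then
  points; failing that, a qualitative severity phrase near the trigger.
  Values outside [0, 100] are rejected.  The qualitative map is
  severely/moderately reduced → below 40%, normal/preserved → not below,
  mildly reduced → indeterminate; the mapping is intentionally conservative
  and lives in one table in `extraction.py`.
- **Medications.** Case-insensitive word-boundary matching over 18 ACEI/ARB
  generics plus common brands and class-level phrases ("ACE inhibitor",
  "ARB"); every surface form maps to exactly one generic (validated at
  load).
- **Context.** A trigger-and-scope rule in the NegEx tradition: negation
  triggers ("no", "not on", "denies", "without") govern forward within the
  clause; discontinuation triggers ("held", "stopped", "discontinued",
  "allergic to", "contraindicated", "refused") govern on either side;
  clause boundaries ("but", "however", ";", ":") end scope.
  Contraindication and refusal are treated as discontinuation because both
  imply the drug is not actually prescribed.
- **RNM.** Eight reason categories (allergy/intolerance, angioedema,
  hyperkalemia — including a K ≥ 5.5 lab-value pattern — renal
  dysfunction, hypotension, refusal, comfort care, other).  A reason phrase
  becomes a mention only when its sentence also references an ACEI/ARB or
  carries a stop/avoid trigger; a specific category suppresses the generic
  "contraindicated" phrase in the same sentence.  The trigger vocabulary is
  explicitly a configuration artifact — reasons-not-to-prescribe are the
  least standardized concept in this domain, and the starter set makes no
  claim of completeness on real text.

Sentence segmentation is a small abbreviation-aware splitter (newlines are
hard boundaries, dotted clinical shorthand like "b.i.d." never splits); the
extractors need no syntactic parses, so none are computed.

## Evaluation statistics

Proportions are reported as percentages with exact two-sided 95% binomial
(Clopper-Pearson) intervals from beta quantiles:
`low = BetaInv(α/2; x, n−x+1)`, `high = BetaInv(1−α/2; x+1, n−x)`, with the
boundary conventions low = 0 at x = 0 and high = 100 at x = n.  The exact
interval was chosen because it is conservative and matches the asymmetric
intervals customarily printed in clinical-NLP evaluations; a Wilson score
interval is available behind a flag for comparison.  A zero denominator
raises `UndefinedMetricError` rather than returning a number.

F-measure is the harmonic mean of sensitivity and PPV on the percent scale
(0 by convention when both are 0).  Cohen's kappa is unweighted,
`(p_o − p_e)/(1 − p_e)` with `p_e` from marginal products, and undefined
when `p_e = 1`; it is cross-checked against an independent implementation
in the tests.  The patient-level report has five fixed rows — measure met,
LVSF assessed, EF <40%, ACEI/ARB, RNM — with SN/SP/PPV/CI/F each; display
rounding is 1–2 decimals, machine output keeps full precision.

## The synthetic corpus generator

The generator's purpose is to make the whole pipeline testable without
clinical data.  Per patient it samples a latent truth and renders it:

| parameter | default | meaning |
|---|---|---|
| `p_ef_documented` | 0.93 | EF appears somewhere in the record |
| `p_ef_lt40_given_documented` | 0.50 | documented EF is below 40% |
| `p_on_med_given_lt40` | 0.85 | ACEI/ARB at discharge when EF <40% |
| `p_rnm_given_lt40_no_med` | 0.50 | RNM inside the branch where it decides the label |
| `p_rnm_overall_target` | 0.149 | overall RNM prevalence (the contraindication rate reported in the heart-failure literature) |
| `p_on_med_otherwise` | 0.25 | ACEI/ARB without reduced EF (common antihypertensives) |
| `notes_per_patient` | 3–8 | uniform; a `heavy()` preset uses 30–50, close to real discharge bundles |
| `variant_noise_rate` | 0.0 | fraction of concepts rendered outside the extractor's patterns |

The branch probabilities were chosen once so that all four classification
branches are well populated at a few hundred patients (expected met rate
≈ 0.895); a `va_prevalence()` preset shifts them toward the ~92% met rate
typical of VA inpatient HF cohorts.  The two RNM parameters are reconciled
by fixing the in-branch rate and solving the out-of-branch rate so the
overall prevalence equals the target in expectation (clipped to [0, 1]).

Rendering places concepts where they are found in real notes: EF in the
echocardiogram narrative summary and in assessment/current-history
sections, medications in medication and assessment sections, RNM in
assessment sections.  Canonical templates are exactly invertible: the
rendered span equals the extractor's span and the parsed value equals the
planted one, which is what makes the end-to-end sensitivity = PPV = 100%
property exact rather than approximate.  Gold records every planted
mention (including negated/discontinued ones, flagged) and a patient-level
determination computed from the latent truth by the same boolean formula
as the classifier; the tests re-derive that formula independently.

Noise decisions are drawn from a dedicated RNG stream (a separate
`SeedSequence` spawn) with one uniform draw per rendering occasion, so at
a fixed seed the set of noise-rendered concepts is nested as the rate
grows.  Lost evidence can only demote predictions from MET to NOT_MET, so
per-seed pipeline sensitivity is monotonically non-increasing in the noise
rate and PPV is unaffected — both are asserted in the tests.

**What the generator does not emulate**: real lexical variety (the
canonical corpus is template-rendered, so perfect extraction there says
nothing about recall on real notes — published ML extractors on real VA
text reach high-90s recall for EF and medications but only ~27–40% for
RNM), misspellings, copy-forward, contradictory documentation, PHI, or the
~42-notes-per-patient density of real records (available via `heavy()` but
not the default, for runtime).  Passing the end-to-end tests demonstrates
the correctness of the plumbing, the roll-up rules, the measure logic, and
the statistics — not clinical-grade extraction performance.

## Numerical and I/O choices

- Character offsets are 0-based half-open, counted after newline
  normalization to `\n`; every stored span re-slices to its evidence text.
- Timestamps are ISO-8601; unparseable or missing dates make a note sort
  before all dated notes, with a warning.
- The corpus on disk is a diffable `metadata.tsv` plus one UTF-8 text file
  per note; results and gold are JSON-lines with a leading schema record.
  A BRAT-style `.ann` import covers externally produced standoff
  annotations (spans validated against the note, mismatches are errors);
  XML exports from desktop annotation tools are deliberately unsupported.
- Problem sizes in the test suite (up to 500 patients, 20 seeds for the
  stochastic recovery check) keep the full suite under a minute while
  leaving Monte-Carlo intervals tight enough to be meaningful.

## Known limitations

- The section-header and "current history" inventories are a dialect table,
  not a learned model; sites must extend them (`--headers`).
- The EF chooser assumes one discharge per patient bundle; longitudinal
  records need pre-splitting.
- Qualitative "mildly reduced" maps to indeterminate rather than a value;
  a site preferring a numeric surrogate must edit the mapping.
- Kappa on real structured-vs-text comparisons depends entirely on the
  structured source's capture quality; the operation is provided, but no
  particular agreement level should be expected.
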