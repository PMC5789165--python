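# Reason-no-medication (RNM) trigger patterns.
# Columns: category <TAB> regex (case-insensitive).
# The vocabulary is a curated starter set and is expected to be extended per
# site; a reason phrase only becomes an RNM mention when its sentence also
# references an ACEI/ARB or carries a stop/avoid trigger.
allergy_intolerance	\ballerg(?:y|ic|ies)\b
allergy_intolerance	\bintoleran(?:ce|t)\b
allergy_intolerance	\bunable\s+to\s+tolerate\b
angioedema	\bangio\s?edema\b
hyperkalemia	\bhyperkal[ae]mia\b
hyperkalemia	\b(?:elevated|high|rising)\s+potassium\b
hyperkalemia	\bK\+?\s*(?:of\s*)?(?:5\.[5-9]|[6-9](?:\.\d)?)\b
hyperkalemia	\bpotassium\s*(?:of\s*)?(?:5\.[5-9]|[6-9](?:\.\d)?)\b
renal_dysfunction	\brenal\s+(?:insufficiency|dysfunction|failure|impairment)\b
renal_dysfunction	\bworsening\s+renal\s+function\b
renal_dysfunction	\b(?:rising|elevated|increasing)\s+creatinine\b
renal_dysfunction	\bacute\s+kidney\s+injury\b|\bAKI\b
renal_dysfunction	\bCKD\b|\bchronic\s+kidney\s+disease\b
hypotension	\bhypotens(?:ion|ive)\b
hypotension	\blow\s+blood\s+pressure\b
hypotension	\bSBP\s*(?:of\s*)?[5-8]\d\b
patient_refusal	\b(?:refus(?:es|ed|ing|al)|declin(?:es|ed|ing))\b
comfort_care	\bcomfort\s+(?:care|measures)\b
comfort_care	\bhospice\b
comfort_care	\bpalliative\b
other_documented_reason	\bcontraindicat(?:ed|ion|ions)\b
other_documented_reason	\bnot\s+a\s+candidate\b
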