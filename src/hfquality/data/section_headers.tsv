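# Section header dialect table.
# Columns: label <TAB> regex (matched case-insensitively at line start) <TAB> doc_types
# doc_types is "*" or a comma-separated list of document type values; rows are
# tried in file order, so doc-type-specific rows should precede wildcard rows.
echo_narrative_summary	^(CONCLUSIONS?|IMPRESSION|INTERPRETATION SUMMARY)\s*:	echocardiogram
echo_results	^(FINDINGS|MEASUREMENTS|ECHO RESULTS|RESULTS|LEFT VENTRICLE)\s*:	echocardiogram
current_history	^(HPI|HISTORY OF PRESENT ILLNESS|INTERVAL HISTORY|HISTORY)\s*:	*
assessment	^(ASSESSMENT( AND PLAN)?|ASSESSMENT/PLAN|A/P|A&P|IMPRESSION|IMPRESSION AND PLAN|HOSPITAL COURSE)\s*:	*
medications	^((DISCHARGE|CURRENT|ACTIVE|HOME|ADMISSION)\s+)?(MEDICATIONS?|MEDS)( RECONCILED| RECONCILIATION)?\s*:	*
medications	^MEDICATION RECONCILIATION\s*:	*
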