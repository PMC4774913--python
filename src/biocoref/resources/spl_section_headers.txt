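# Structured drug label section headers, matched at line starts.
DRUG INTERACTIONS
PRECAUTIONS
WARNINGS
CONTRAINDICATIONS
ADVERSE REACTIONS
CLINICAL PHARMACOLOGY
DOSAGE AND ADMINISTRATION
INDICATIONS AND USAGE
OVERDOSAGE
DESCRIPTION
HOW SUPPLIED
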