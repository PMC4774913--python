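# Meronyms and event triggers that coerce a possessive pronoun toward
# the gene/protein group.
residue
residues
domain
domains
binding
expression
interaction
regulation
activity
localization
phosphorylation
transactivation
transcription
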