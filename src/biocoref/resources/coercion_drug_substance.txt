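# Headwords that coerce a possessive pronoun toward the drug/substance group.
effect
effects
absorption
clearance
safety
moiety
metabolism
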