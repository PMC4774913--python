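# Singular-form nouns treated as plural for number agreement.
family
population
group
staff
team
majority
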