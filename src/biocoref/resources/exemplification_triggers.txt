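# Phrases introducing exemplifications of a broader class.
e.g.
e.g
such as
including
for example
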