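# Sentence-initial discourse connectives licensing pronominal cataphora.
because
because of
although
since
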