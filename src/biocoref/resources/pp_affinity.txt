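# noun preposition pairs: a preposition parsed as attached to a verb is
# re-attached to an immediately preceding noun on this list.
effect of
effects of
interaction with
interactions with
dose of
component of
inhibitor of
inhibitors of
metabolism of
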