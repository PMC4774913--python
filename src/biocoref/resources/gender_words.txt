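# word gender
mother Female
daughter Female
sister Female
wife Female
woman Female
father Male
son Male
brother Male
husband Male
man Male
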