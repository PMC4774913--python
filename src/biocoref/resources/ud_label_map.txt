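# Universal Dependencies -> Stanford-style dependency labels.
# One mapping per line: UD_LABEL STANFORD_LABEL
nsubj:pass nsubjpass
csubj:pass csubjpass
obj dobj
obl pobj
obl:agent pobj
nmod prep
nmod:poss poss
acl vmod
acl:relcl rcmod
aux:pass auxpass
compound nn
flat nn
fixed mwe
case prep
cc:preconj preconj
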