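"""Score predicted coreference chains against gold with the standard
metrics (MUC, B-CUBED, CEAF, BLANC) and their unweighted F1 average."""

from biocoref import chain_metrics

gold = [frozenset({"m1", "m2", "m3"}), frozenset({"m4", "m5"})]
pred = [frozenset({"m1", "m2"}), frozenset({"m3", "m4", "m5"})]

report = chain_metrics(gold, pred)
for name, prf in (
    ("MUC", report.muc),
    ("B-CUBED", report.bcubed),
    ("CEAF", report.ceaf),
    ("BLANC", report.blanc),
):
    print(f"{name:<8} P={prf.precision:.3f} R={prf.recall:.3f} F1={prf.f1:.3f}")
print(f"average F1 over MUC, B-CUBED, CEAF: {report.average_f1:.3f}")
# MUC counts link edits, B-CUBED averages per-mention chain overlap, CEAF
# aligns chains one-to-one, BLANC averages the coreferent and
# non-coreferent link classes; the headline number is the unweighted mean
# of the first three F1 scores.
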