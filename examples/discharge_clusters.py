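"""Cluster-mode resolution in the style of clinical discharge summaries.

Builds a sectioned note with gold mention spans (the setting in which
mentions are given and only clustering is evaluated), types them, runs the
discharge configuration, and prints the resulting mention clusters.
"""

from biocoref import load_configuration, run_pipeline, type_gold_mentions
from biocoref.fixtures import build_document
from biocoref.preprocessing import preprocess
from biocoref.types import Span

sents = [
    ([("ADMISSION", "NN"), ("MEDICATIONS", "NNS", "medication"), (":", ":")],
     [("nn", 1, 0), ("punct", 1, 2)]),
    (
        [("The", "DT"), ("patient", "NN"), ("was", "VBD", "be"),
         ("started", "VBN", "start"), ("on", "IN"), ("coumadin", "NN"), (".", ".")],
        [("det", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2),
         ("prep", 3, 4), ("pobj", 4, 5), ("punct", 3, 6)],
    ),
    ([("DISCHARGE", "NN"), ("MEDICATIONS", "NNS", "medication"), (":", ":")],
     [("nn", 1, 0), ("punct", 1, 2)]),
    (
        [("Continue", "VB"), ("coumadin", "NN"), ("daily", "RB"), (".", ".")],
        [("dobj", 0, 1), ("advmod", 0, 2), ("punct", 0, 3)],
    ),
    (
        [("The", "DT"), ("patient", "NN"), ("will", "MD"), ("follow", "VB"),
         ("up", "RP"), (".", ".")],
        [("det", 1, 0), ("nsubj", 3, 1), ("aux", 3, 2), ("prt", 3, 4),
         ("punct", 3, 5)],
    ),
]
doc = build_document(sents).doc
preprocess(doc, section_mode="discharge")
text = doc.text


def span(sub, start=0):
    i = text.index(sub, start)
    return Span(i, i + len(sub))


gold_spans = [
    span("The patient"),
    span("coumadin"),
    span("coumadin", text.index("Continue")),
    span("The patient", text.index("DISCHARGE")),
]
mentions = type_gold_mentions(
    gold_spans, doc, semtypes=["person", "treatment", "treatment", "person"]
)

config = load_configuration("discharge")
chains = run_pipeline(doc, config, mentions=mentions)
for i, chain in enumerate(chains, 1):
    members = ", ".join(repr(doc.slice(m.span)) for m in chain.members)
    print(f"cluster {i}: {members}")
# The coumadin cluster comes from an exact-string anaphora link; the
# patient cluster is assembled by the cross-section merge step, since
# section-window strategies never link across section boundaries.
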