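"""Generate a small synthetic corpus and summarize its planted structure.

Writes nothing to disk; shows the per-coreference-type and per-mention-type
counts that the generator planted, which downstream tests use as gold.
"""

from biocoref import FixtureSpec, corpus_stats, generate

docs = [
    generate(
        FixtureSpec(
            anaphora=2, cataphora=1, appositive=1, predicate_nominative=1,
            set_membership=1, seed=seed,
        )
    )
    for seed in range(10)
]
stats = corpus_stats(docs)

print("gold links per coreference type:")
for ctype, n in sorted(stats["ctype"].items()):
    print(f"  {ctype:<22} {n}")
print("gold mentions per mention type:")
for mtype, n in sorted(stats["mtype"].items()):
    print(f"  {mtype:<22} {n}")
# Set-membership instances appear as anaphora links split per conjunct, so
# the anaphora count exceeds the number of anaphoric mentions.
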