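"""Inspect the reward/penalty scoring of candidate antecedents.

Builds a two-sentence fragment with a singular drug and a pronoun anaphor,
then prints the per-method agreement outcomes and the cumulative score for
each candidate under the personal-pronoun anaphora strategy.
"""

from biocoref import (
    CoreferenceType,
    FixtureSpec,
    MentionType,
    agree,
    detect_mentions,
    generate,
    load_configuration,
    score_candidate,
)
from biocoref.preprocessing import preprocess

g = generate(FixtureSpec(anaphora=1, mention_types=("PersonalPronoun",), seed=2))
doc = preprocess(g.doc)
doc.mentions = detect_mentions(doc)
mention = next(m for m in doc.mentions if m.mtype is MentionType.PersonalPronoun)
config = load_configuration("spl")
strategy = next(
    s
    for s in config.strategies
    if s.ctype is CoreferenceType.anaphora and MentionType.PersonalPronoun in s.mtypes
)

print(doc.text)
print(f"anaphor: {doc.slice(mention.span)!r}")
for cand in doc.entities:
    print(f"\ncandidate: {doc.slice(cand.span)!r}")
    for spec in strategy.scoring:
        ok = agree(spec.method, mention, cand, doc)
        delta = f"+{spec.reward}" if ok else f"-{spec.penalty}"
        print(f"  {spec.method:<10} {'agree' if ok else 'disagree':<9} {delta}")
    total = score_candidate(mention, cand, strategy.scoring, doc).score
    threshold = strategy.postscoring[0].parameter
    verdict = "passes" if total >= threshold else "fails"
    print(f"  cumulative score {total} ({verdict} Threshold({threshold}))")
# A candidate agreeing on person, gender, animacy and number scores 4 and
# passes the threshold; any single disagreement leaves it below.
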