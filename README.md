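# biocoref

Rule-based, strategy-driven coreference resolution for biomedical text.

Biomedical documents — drug labels, clinical discharge summaries, molecular
biology abstracts — refer back (and forward) to drugs, substances, proteins
and clinical entities with pronouns ("it", "its"), definite and
demonstrative noun phrases ("the drug", "these isoenzymes"), appositives
("the ACE inhibitor enalapril") and copular constructions ("Clopidogrel is
a prodrug"). Resolving these references is a prerequisite for relation
extraction tasks such as drug–drug interaction mining, yet each combination
of coreference type and mention type needs a different treatment.

`biocoref` organizes resolution as a set of declarative **strategies**, one
per coreference-type/mention-type pair. A strategy names:

* **mention filters** — drop non-coreferential mentions (pleonastic *it*,
  rigid designators, appositive NPs, first/second-person pronouns);
* **candidate filters** — restrict the referent pool (prior/subsequent
  discourse, sentence/section windows, a syntactic i-within-i-style filter,
  exemplification removal);
* a **scoring function** — an ordered list of agreement methods
  `Method(reward, penalty)`; a candidate *c* for mention *m* accumulates

  ```
  SC_0(c, m) = 0
  SC_k(c, m) = SC_{k-1}(c, m) + Rew(AM_k)   if AM_k(c, m)
             = SC_{k-1}(c, m) - Pen(AM_k)   otherwise
  ```

  over methods such as Number/Person/Gender/Animacy agreement, hypernym
  lists, string measures (ExactString, PreModifierAndHead, RelaxedStem),
  syntactic appositive/predicate-nominative tests, discourse connectives,
  semantic coercion and taxonomy lookup;
* **post-scoring filters** — `Threshold(t)`, `TopScore`, and `Salience`
  (textual proximity, or dependency-parse distance with +2 per intervening
  sentence).

Three bundled configurations reproduce published strategy tables for
structured drug labels (`spl`), discharge summaries (`discharge`, cluster
output with cross-section merging and a patient cluster) and a protein
coreference dataset (`protein`). The package also ships CoNLL-U and brat
standoff readers/writers, the standard coreference metrics (pairwise
P/R/F1 with exact or approximate span matching; MUC, B-CUBED, CEAF, BLANC
and their unweighted F1 average), and a deterministic synthetic fixture
generator so everything is testable without corpus downloads.

## Worked example

```bash
python examples/resolve_drug_label.py
```

generates a small parsed drug-label document with planted coreference and
resolves it with the `spl` configuration:

```
type                   mention                referent
anaphora               It                     triamterene
anaphora               Its                    diltiazem
anaphora               The drug               bisoprolol
cataphora              it                     benazepril
cataphora              its                    amiodarone
anaphora               these isoenzymes       CYP2C8
anaphora               these isoenzymes       CYP3A4
appositive             the ACE inhibitor      lisinopril
predicate_nominative   a prodrug              digoxin
------------------------------------------------------------
planted links recovered: 9/9
```

Each line is a typed mention–referent link; the demonstrative NP resolves
to both members of a coordinated enzyme pair (set-membership coreference,
split into one link per conjunct), and the final line checks the output
against the generator's gold annotation. `examples/score_candidates.py`
prints the per-method agreement ledger behind one such decision — a
candidate agreeing on person, gender, animacy and number scores exactly 4
and passes `Threshold(4)`; `examples/discharge_clusters.py` and
`examples/evaluate_chains.py` show cluster-mode resolution and the chain
metrics.

A thin CLI wraps the same machinery:

```bash
biocoref simulate --out data --n-docs 5 --seed 1
biocoref resolve  --config spl --input data --parses data --out pred
biocoref evaluate --gold data --pred pred
```

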