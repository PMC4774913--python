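# Methods

## Model

Coreference resolution is treated as a pipeline of deterministic,
independently configurable steps. The unit of processing is a `Document`:
raw text, sentences with tokens (lemma, Penn POS, character offsets) and a
labelled dependency graph, named entities carrying a fine semantic type and
a coarse semantic group, plus layers computed by the pipeline
(coordinations, sections, discourse-level conjunct sets, mentions).
Character offsets are 0-based half-open everywhere; brat standoff offsets
are consumed as-is.

Resolution proceeds left to right over detected (or supplied) mentions.
For each mention, every strategy registered for its mention type runs:
candidate filters shrink an initial pool (entities, coordinations,
discourse conjunct sets, other coreferential mentions, verb heads) in the
listed order; each surviving candidate receives the cumulative
reward/penalty score `SC_k`; post-scoring filters (threshold, top score,
salience) select at most one referent; a surviving referent yields one
typed link per (mention, strategy). Pruning then arbitrates: a pronoun
holding both an anaphoric and a cataphoric link keeps only the cataphoric
one, and a non-empty semantic-group whitelist removes links whose referent
group falls outside it. Output is either pairwise links (coordination
referents split into one link per conjunct) or clusters (union-find over
pairs, with absorption of interleaved same-type substring mentions).

The assumptions are those of a deterministic, lexico-syntactic approach:
correct-enough parses, entity annotations with semantic types, and lexical
resources (hypernym lists, coercion triggers, connectives) appropriate to
the text genre. No statistical model is trained anywhere.

## Parameters that matter

* **Reward/penalty weights and thresholds** come from the bundled
  configuration tables. In the drug-label configuration the pronoun
  strategies use four phi agreements at (1,0) with `Threshold(4)`: all four
  must agree and a candidate meeting them scores exactly the threshold
  (threshold semantics are *keep score >= t*). Nominal anaphora uses
  `Number(1,1) + HypernymList(3,0)` with `Threshold(4)`: a hypernym match is
  necessary and a number clash is disqualifying.
* **Window sizes** are measured in sentences; `WindowSize(k)` spans the
  mention's sentence plus k−1 neighbouring sentences in the filter's
  direction, `Sentence`/`Section`/`Document` widen accordingly.
* **Salience.** `Default` counts intervening tokens (flat across sentence
  boundaries — the smallest textual unit gives a strict order). `Parse` is
  the undirected dependency-path length between the two heads within a
  sentence; across sentences it is the sum of each head's depth to its
  sentence root plus 2 per sentence of separation, and ties fall back to
  `Default`. A disconnected node receives the sentence token count as a
  documented sentinel. Final ties are broken by span-start distance, then
  leftmost candidate, so resolution is deterministic.
* **RelaxedStem** stems content words (determiners, pronouns and
  prepositions excluded) with the Porter algorithm and declares
  compatibility when `|shared| / max(|A|, |B|)` strictly exceeds 0.5; the
  max denominator is the conservative choice and makes the boundary
  directly testable. Numeric tokens must match exactly.
* **Lexical resources** are plain-text files under
  `src/biocoref/resources/` (per-group hypernym headwords, semantic-coercion
  triggers, discourse connectives, gender words, collective nouns, section
  headers, PP-attachment affinities, exemplification triggers) and can be
  overridden by passing explicit resources. The toy concept taxonomy is a
  synthetic stand-in exercising the `is_ancestor` interface; real
  deployments plug in a terminology service.

## Pre-processing

Six graph transformations run in a fixed order. Semantic enrichment
collapses each multi-token entity onto its head token (rightmost non-punct
token), deleting intra-entity edges — it is idempotent. PP-attachment
correction re-attaches a verb-attached preposition to an immediately
preceding noun when a configured (noun, preposition) affinity licenses it.
Modifier and term coordination are corrective heuristics: the former
re-points a conj edge onto an entity pre-modifier, the latter adds missing
conj edges along serial comma lists (three or more entity conjuncts,
parenthetical asides skipped). Coordination re-heads conjuncts onto the
overt conjunction token via `conj_arg` edges, so paths to a coordination
pass through one node. NP-internal chunking is dependency-based: a chunk is
a nominal head plus its contiguous left modifiers (tokens absorbed into a
merged entity node count as part of that node); of-PPs are excluded, so the
head is the chunk's rightmost token. This head rule mis-heads coordinated
NPs whose true head follows the conjuncts (e.g. "... and benzothiazepine
*classes*") — a known limitation inherited by mention filtering.

Coordinated entities sharing a semantic type or group become `Conjunction`
candidates (number: plural). Section segmentation matches a configured
header list at line starts (drug labels) or marks a line whose last token
is a colon and which contains a capitalized word (discharge summaries).
Discourse-level list recognition collects, per section and semantic group,
entities that are the first element on their line (list bullets stripped),
adding same-line coordinated partners; the resulting conjunct sets serve
itemized-list cataphora.

## Mention detection decisions

The pleonastic-*it* rule requires *it* in (passive) subject position under
a governor that also takes a clausal complement (infmod/ccomp/xcomp/vmod);
the variant that instead requires a dependent *outside* that label set is
available via `strict_negated_rule` but over-fires on ordinary referential
subjects, so the complement-presence reading is the default. A
definite/demonstrative NP is a rigid designator when its head token lies
inside an entity annotation or its determiner-stripped string matches an
entity string elsewhere in the document. Appositive membership is detected
by appos/abbrev edges or by contiguity with an entity across only
punctuation. Demonstrative-versus-NP conflicts prefer the NP reading when a
nominal token follows. Candidate pools drop mentions whose head token sits
inside an entity annotation — they duplicate the entity already in the
pool.

## Synthetic fixtures

The generator (`biocoref.fixtures`) emulates the structure of drug-label
text: short sentences with annotated drug/substance entities and one
planted coreference construction per template — pronominal and possessive
anaphora, distributive/reciprocal pronouns, definite/demonstrative/
distributive nominal anaphora (including set membership over a coordinated
enzyme pair), connective-licensed pronominal cataphora, itemized-list
cataphora, contiguous and parenthetical appositives, and copular predicate
nominatives. Templates carry hand-written dependency edges instead of
invoking a parser, so tests are hermetic and parse-error-free; entity names
are drawn from a list of real drug and enzyme names so the bundled hypernym
lexicons are meaningful. Spacer sentences keep instances out of each
other's candidate windows, so `unambiguous` documents have exactly one
fully agreeing candidate per planted mention; `tied` plants two
phi-identical candidates that only salience separates; `subthreshold`
plants mentions whose every candidate fails one agreement and must yield no
link. All randomness flows from the spec seed (template vocabulary
choices), so equal seeds give byte-identical text, CoNLL-U and brat output.

What passing on these fixtures does **not** show: robustness to real parser
errors, to imperfect entity annotation, to long-range discourse structure,
or to the lexical variety of real clinical text — the corpus-level
evaluations require the respective corpora.

## Evaluation

Pairwise scoring follows the typed-link convention: a predicted link is
correct when a gold link of the same coreference type matches both elements
(exact span equality or span overlap for approximate matching), with
maximum bipartite matching so each gold link is used once; empty gold and
empty prediction score 1 by convention. Chain metrics: MUC (link-based),
B-CUBED (per-mention), CEAF with mention-based similarity by default
(entity-based behind a switch; the choice is stated in the CLI help) via an
assignment solver, and BLANC in its original two-class Rand-style
definition (the extended variant is not implemented). Unclustered mentions
of either side are treated as singletons; the headline number is the
unweighted mean of the MUC, B-CUBED and CEAF F1 scores.

## Problem sizes

The test suite and acceptance script run on generated documents of roughly
10–40 sentences. The planted-link recovery check uses 100 seeded
unambiguous documents (about 19 sentences each) plus 20 subthreshold
documents; metric correctness is verified against brute-force
reimplementations on 50 random partitions of up to 8 mentions. These sizes
exercise every strategy of the drug-label configuration while keeping the
whole suite in the seconds range.

## Known limitations

* Exemplification detection is offset-based (brackets and trigger phrases
  bounded by the next verb), not parse-based; unusual punctuation defeats
  it.
* The contiguity fallback for appositives fires across any
  punctuation-only gap and can create spurious appositive links (e.g.
  after a serial comma).
* Semantic knowledge is list-based; hypernym or coercion gaps translate
  directly into recall loss, and no concept normalization is performed.
* Cluster merging is greedy in document order with exact-string evidence
  only; no acronym handling, spelling correction, or external knowledge.
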