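"""Deterministic synthetic fixture generator.

Builds small, entity-annotated, dependency-parsed documents in the style
of structured drug labels, with coreference of every supported type
planted from hand-written sentence templates (pronominal anaphora,
possessive anaphora, distributive/reciprocal pronouns, definite and
demonstrative nominal anaphora over coordinations, connective-licensed
cataphora, itemized-list cataphora, contiguous and parenthetical
appositives, copular predicate nominatives).

Templates carry hand-written dependency edges rather than invoking a
parser, so tests are hermetic; gold annotations exactly reflect the
planted structure.  All randomness is derived from the spec seed, so the
same seed yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .brat_io import write_brat
from .conllu_io import write_conllu
from .types import (
    Chain,
    CoreferenceLink,
    CoreferenceType,
    DependencyGraph,
    Document,
    Entity,
    Mention,
    MentionType,
    Sentence,
    Span,
    Token,
)

DRUGS = [
    "amiodarone", "warfarin", "clopidogrel", "digoxin", "metoprolol",
    "lisinopril", "furosemide", "heparin", "diltiazem", "verapamil",
    "amlodipine", "bisoprolol", "enalapril", "torsemide", "aliskiren",
    "valsartan", "benazepril", "spironolactone", "amiloride", "triamterene",
]
ENZYMES = ["CYP3A4", "CYP2C8", "CYP2C9", "CYP2D6", "CYP1A2", "CYP2B6"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """What to plant: counts per coreference type, ambiguity regime, seed."""

    anaphora: int = 0
    cataphora: int = 0
    appositive: int = 0
    predicate_nominative: int = 0
    set_membership: int = 0
    distractors: int = 0
    ambiguity: str = "unambiguous"  # unambiguous | tied | subthreshold
    seed: int = 0
    mention_types: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        for f in ("anaphora", "cataphora", "appositive",
                  "predicate_nominative", "set_membership", "distractors"):
            if getattr(self, f) < 0:
                raise FixtureError(f"negative count for {f}")
        if self.ambiguity not in ("unambiguous", "tied", "subthreshold"):
            raise FixtureError(f"unknown ambiguity level {self.ambiguity!r}")


@dataclass
class GeneratedDocument:
    doc: Document
    entities: list[Entity]
    mentions: list[Mention]
    links: list[CoreferenceLink]  # gold, conjunctions split per conjunct
    chains: list[Chain]
    conllu: str
    brat_txt: str
    brat_ann: str


# --------------------------------------------------------------------- #
# template bodies
#
# A template instance is a dict with local sentence/token coordinates:
#   sentences: [(tokens, edges)]       tokens: (text, pos[, lemma])
#   entities:  [(sent, lo, hi, semtype)]
#   mentions:  [(sent, lo, hi, MentionType)]
#   links:     [(CoreferenceType, mention_index, [entity_index, ...])]


def _tok(t):
    if len(t) == 2:
        return (t[0], t[1], t[0].lower())
    return t


def _prior_sentence(x: str):
    return (
        [
            ("Patients", "NNS", "patient"), ("received", "VBD", "receive"),
            (x, "NN"), ("daily", "RB"), (".", "."),
        ],
        [("nsubj", 1, 0), ("dobj", 1, 2), ("advmod", 1, 3), ("punct", 1, 4)],
    )


def _coordinated_prior(x: str, y: str):
    return (
        [
            ("Patients", "NNS", "patient"), ("received", "VBD", "receive"),
            (x, "NN"), ("and", "CC"), (y, "NN"),
            ("concomitantly", "RB"), (".", "."),
        ],
        [
            ("nsubj", 1, 0), ("dobj", 1, 2), ("cc", 2, 3), ("conj", 2, 4),
            ("advmod", 1, 5), ("punct", 1, 6),
        ],
    )


def t_anaphora_personal(rng, ambiguity):
    x = rng.choice(DRUGS)
    if ambiguity == "tied":
        y = rng.choice([d for d in DRUGS if d != x])
        s1 = (
            [
                ("Patients", "NNS", "patient"), ("received", "VBD", "receive"),
                (x, "NN"), ("before", "IN"), (y, "NN"), (".", "."),
            ],
            [
                ("nsubj", 1, 0), ("dobj", 1, 2), ("prep", 1, 3),
                ("pobj", 3, 4), ("punct", 1, 5),
            ],
        )
        s2 = (
            [("It", "PRP", "it"), ("was", "VBD", "be"),
             ("discontinued", "VBN", "discontinue"), (".", ".")],
            [("nsubjpass", 2, 0), ("auxpass", 2, 1), ("punct", 2, 3)],
        )
        # parse salience prefers the shallower direct object
        return {
            "sentences": [s1, s2],
            "entities": [(0, 2, 3, "drug"), (0, 4, 5, "drug")],
            "mentions": [(1, 0, 1, MentionType.PersonalPronoun)],
            "links": [(CoreferenceType.anaphora, 0, [0])],
        }
    pron = "They" if ambiguity == "subthreshold" else "It"
    s2 = (
        [
            (pron, "PRP", pron.lower()), ("increased", "VBD", "increase"),
            ("bleeding", "NN"), ("risk", "NN"), (".", "."),
        ],
        [("nsubj", 1, 0), ("nn", 3, 2), ("dobj", 1, 3), ("punct", 1, 4)],
    )
    links = [] if ambiguity == "subthreshold" else [
        (CoreferenceType.anaphora, 0, [0])
    ]
    return {
        "sentences": [_prior_sentence(x), s2],
        "entities": [(0, 2, 3, "drug")],
        "mentions": [(1, 0, 1, MentionType.PersonalPronoun)],
        "links": links,
    }


def t_anaphora_possessive(rng, ambiguity):
    x = rng.choice(DRUGS)
    pron = "Their" if ambiguity == "subthreshold" else "Its"
    s2 = (
        [
            (pron, "PRP$", pron.lower()), ("absorption", "NN"),
            ("was", "VBD", "be"), ("reduced", "VBN", "reduce"), (".", "."),
        ],
        [("poss", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2), ("punct", 3, 4)],
    )
    links = [] if ambiguity == "subthreshold" else [
        (CoreferenceType.anaphora, 0, [0])
    ]
    return {
        "sentences": [_prior_sentence(x), s2],
        "entities": [(0, 2, 3, "drug")],
        "mentions": [(1, 0, 1, MentionType.PossessivePronoun)],
        "links": links,
    }


def t_anaphora_definite(rng, ambiguity):
    x = rng.choice(DRUGS)
    head = ("tablets", "NNS", "tablet") if ambiguity == "subthreshold" else (
        "drug", "NN", "drug"
    )
    s2 = (
        [
            ("The", "DT", "the"), head, ("increased", "VBD", "increase"),
            ("bleeding", "NN"), ("risk", "NN"), (".", "."),
        ],
        [
            ("det", 1, 0), ("nsubj", 2, 1), ("nn", 4, 3), ("dobj", 2, 4),
            ("punct", 2, 5),
        ],
    )
    links = [] if ambiguity == "subthreshold" else [
        (CoreferenceType.anaphora, 0, [0])
    ]
    return {
        "sentences": [_prior_sentence(x), s2],
        "entities": [(0, 2, 3, "drug")],
        "mentions": [(1, 0, 2, MentionType.DefiniteNP)],
        "links": links,
    }


def t_anaphora_distributive_pronoun(rng, ambiguity):
    x, y = rng.sample(DRUGS, 2)
    s2 = (
        [
            ("Both", "DT", "both"), ("were", "VBD", "be"), ("well", "RB"),
            ("tolerated", "VBN", "tolerate"), (".", "."),
        ],
        [("nsubjpass", 3, 0), ("auxpass", 3, 1), ("advmod", 3, 2), ("punct", 3, 4)],
    )
    return {
        "sentences": [_coordinated_prior(x, y), s2],
        "entities": [(0, 2, 3, "drug"), (0, 4, 5, "drug")],
        "mentions": [(1, 0, 1, MentionType.DistributivePronoun)],
        "links": [(CoreferenceType.anaphora, 0, [0, 1])],
    }


def t_anaphora_distributive_np(rng, ambiguity):
    x, y = rng.sample(DRUGS, 2)
    s2 = (
        [
            ("Both", "DT", "both"), ("drugs", "NNS", "drug"),
            ("were", "VBD", "be"), ("well", "RB"),
            ("tolerated", "VBN", "tolerate"), (".", "."),
        ],
        [
            ("det", 1, 0), ("nsubjpass", 4, 1), ("auxpass", 4, 2),
            ("advmod", 4, 3), ("punct", 4, 5),
        ],
    )
    return {
        "sentences": [_coordinated_prior(x, y), s2],
        "entities": [(0, 2, 3, "drug"), (0, 4, 5, "drug")],
        "mentions": [(1, 0, 2, MentionType.DistributiveNP)],
        "links": [(CoreferenceType.anaphora, 0, [0, 1])],
    }


def t_anaphora_reciprocal(rng, ambiguity):
    x, y = rng.sample(DRUGS, 2)
    s1 = (
        [
            ("Concomitant", "JJ"), (x, "NN"), ("and", "CC"), (y, "NN"),
            ("may", "MD"), ("interact", "VB"), ("with", "IN"),
            ("each", "DT"), ("other", "JJ"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("cc", 1, 2), ("conj", 1, 3), ("nsubj", 5, 1),
            ("aux", 5, 4), ("prep", 5, 6), ("pobj", 6, 8), ("dep", 8, 7),
            ("punct", 5, 9),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 1, 2, "drug"), (0, 3, 4, "drug")],
        "mentions": [(0, 7, 9, MentionType.ReciprocalPronoun)],
        "links": [(CoreferenceType.anaphora, 0, [0, 1])],
    }


def t_set_membership(rng, ambiguity):
    x = rng.choice(DRUGS)
    e1, e2 = rng.sample(ENZYMES, 2)
    s1 = (
        [
            ("Oral", "JJ"), (x, "NN"), ("is", "VBZ", "be"),
            ("metabolized", "VBN", "metabolize"), ("by", "IN"), (e1, "NN"),
            ("and", "CC"), (e2, "NN"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2),
            ("prep", 3, 4), ("pobj", 4, 5), ("cc", 5, 6), ("conj", 5, 7),
            ("punct", 3, 8),
        ],
    )
    s2 = (
        [
            ("Such", "JJ", "such"), ("interactions", "NNS", "interaction"),
            ("involve", "VBP"), ("these", "DT", "this"),
            ("isoenzymes", "NNS", "isoenzyme"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubj", 2, 1), ("det", 4, 3), ("dobj", 2, 4),
            ("punct", 2, 5),
        ],
    )
    return {
        "sentences": [s1, s2],
        "entities": [(0, 1, 2, "drug"), (0, 5, 6, "substance"), (0, 7, 8, "substance")],
        "mentions": [(1, 3, 5, MentionType.DemonstrativeNP)],
        "links": [(CoreferenceType.anaphora, 0, [1, 2])],
    }


def t_cataphora_personal(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Although", "IN"), ("it", "PRP"), ("is", "VBZ", "be"),
            ("generally", "RB"), ("safe", "JJ"), (",", ","), (x, "NN"),
            ("may", "MD"), ("cause", "VB"), ("dizziness", "NN"), (".", "."),
        ],
        [
            ("mark", 4, 0), ("nsubj", 4, 1), ("cop", 4, 2), ("advmod", 4, 3),
            ("advcl", 8, 4), ("punct", 8, 5), ("nsubj", 8, 6), ("aux", 8, 7),
            ("dobj", 8, 9), ("punct", 8, 10),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 6, 7, "drug")],
        "mentions": [(0, 1, 2, MentionType.PersonalPronoun)],
        "links": [(CoreferenceType.cataphora, 0, [0])],
    }


def t_cataphora_possessive(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Because", "IN"), ("of", "IN"), ("its", "PRP$"),
            ("beta1-selectivity", "NN"), (",", ","), (x, "NN"),
            ("may", "MD"), ("be", "VB"), ("preferred", "VBN", "prefer"),
            (".", "."),
        ],
        [
            ("prep", 8, 0), ("mwe", 0, 1), ("pobj", 0, 3), ("poss", 3, 2),
            ("punct", 8, 4), ("nsubjpass", 8, 5), ("aux", 8, 6),
            ("auxpass", 8, 7), ("punct", 8, 9),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 5, 6, "drug")],
        "mentions": [(0, 2, 3, MentionType.PossessivePronoun)],
        "links": [(CoreferenceType.cataphora, 0, [0])],
    }


def t_cataphora_definite_list(rng, ambiguity):
    a, b = rng.sample(DRUGS, 2)
    s1 = (
        [
            ("When", "WRB"), ("administered", "VBN", "administer"),
            ("concurrently", "RB"), (",", ","), ("the", "DT"),
            ("following", "JJ"), ("drugs", "NNS", "drug"), ("may", "MD"),
            ("interact", "VB"), (":", ":"),
        ],
        [
            ("advmod", 1, 0), ("advcl", 8, 1), ("advmod", 1, 2),
            ("punct", 8, 3), ("det", 6, 4), ("amod", 6, 5), ("nsubj", 8, 6),
            ("aux", 8, 7), ("punct", 8, 9),
        ],
    )

    def item(drug):
        return (
            [
                ("-", ":"), (drug, "NN"), (":", ":"),
                ("dosage", "NN"), ("adjustment", "NN"), ("may", "MD"),
                ("be", "VB"), ("required", "VBN", "require"), (".", "."),
            ],
            [
                ("punct", 7, 0), ("dep", 7, 1), ("punct", 7, 2),
                ("nn", 4, 3), ("nsubjpass", 7, 4), ("aux", 7, 5),
                ("auxpass", 7, 6), ("punct", 7, 8),
            ],
        )

    return {
        "sentences": [s1, item(a), item(b)],
        "entities": [(1, 1, 2, "drug"), (2, 1, 2, "drug")],
        "mentions": [(0, 4, 7, MentionType.DefiniteNP)],
        "links": [(CoreferenceType.cataphora, 0, [0, 1])],
    }


def t_appositive_definite(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Treatment", "NN"), ("with", "IN"), ("the", "DT"), ("ACE", "NN"),
            ("inhibitor", "NN"), (x, "NN"), ("was", "VBD", "be"),
            ("initiated", "VBN", "initiate"), (".", "."),
        ],
        [
            ("nsubjpass", 7, 0), ("prep", 0, 1), ("pobj", 1, 4), ("det", 4, 2),
            ("nn", 4, 3), ("appos", 4, 5), ("auxpass", 7, 6), ("punct", 7, 8),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 5, 6, "drug")],
        "mentions": [(0, 2, 5, MentionType.DefiniteNP)],
        "links": [(CoreferenceType.appositive, 0, [0])],
    }


def t_appositive_indefinite(rng, ambiguity):
    x = rng.choice(DRUGS)
    e = rng.choice(ENZYMES)
    s1 = (
        [
            ("The", "DT"), ("metabolism", "NN"), ("of", "IN"), (x, "NN"),
            ("(", "-LRB-"), ("a", "DT"), (e, "NN"), ("substrate", "NN"),
            (")", "-RRB-"), ("was", "VBD", "be"),
            ("examined", "VBN", "examine"), (".", "."),
        ],
        [
            ("det", 1, 0), ("nsubjpass", 10, 1), ("prep", 1, 2),
            ("pobj", 2, 3), ("appos", 3, 7), ("det", 7, 5), ("nn", 7, 6),
            ("punct", 7, 4), ("punct", 7, 8), ("auxpass", 10, 9),
            ("punct", 10, 11),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 3, 4, "drug"), (0, 6, 7, "substance")],
        "mentions": [(0, 5, 8, MentionType.IndefiniteNP)],
        "links": [(CoreferenceType.appositive, 0, [0])],
    }


def t_appositive_zero_article(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Oral", "JJ"), (x, "NN"), (",", ","), ("cardiac", "JJ"),
            ("glycoside", "NN"), ("therapy", "NN"), (",", ","),
            ("was", "VBD", "be"), ("continued", "VBN", "continue"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubjpass", 8, 1), ("punct", 1, 2),
            ("appos", 1, 5), ("amod", 5, 3), ("nn", 5, 4), ("punct", 1, 6),
            ("auxpass", 8, 7), ("punct", 8, 9),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 1, 2, "drug")],
        "mentions": [(0, 3, 6, MentionType.ZeroArticleNP)],
        "links": [(CoreferenceType.appositive, 0, [0])],
    }


def t_prednom_indefinite(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Oral", "JJ"), (x, "NN"), ("is", "VBZ", "be"), ("a", "DT"),
            ("prodrug", "NN"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubj", 4, 1), ("cop", 4, 2), ("det", 4, 3),
            ("punct", 4, 5),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 1, 2, "drug")],
        "mentions": [(0, 3, 5, MentionType.IndefiniteNP)],
        "links": [(CoreferenceType.predicate_nominative, 0, [0])],
    }


def t_prednom_zero_article(rng, ambiguity):
    x = rng.choice(DRUGS)
    s1 = (
        [
            ("Oral", "JJ"), (x, "NN"), ("is", "VBZ", "be"),
            ("anticoagulant", "JJ"), ("medication", "NN"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubj", 4, 1), ("cop", 4, 2), ("amod", 4, 3),
            ("punct", 4, 5),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 1, 2, "drug")],
        "mentions": [(0, 3, 5, MentionType.ZeroArticleNP)],
        "links": [(CoreferenceType.predicate_nominative, 0, [0])],
    }


SPACER = (
    [
        ("No", "DT", "no"), ("other", "JJ"), ("information", "NN"),
        ("is", "VBZ", "be"), ("available", "JJ"), (".", "."),
    ],
    [
        ("det", 2, 0), ("amod", 2, 1), ("nsubj", 4, 2), ("cop", 4, 3),
        ("punct", 4, 5),
    ],
)


def t_distractor(rng, ambiguity):
    s1 = (
        [
            ("Severe", "JJ"), ("hypotension", "NN"), ("was", "VBD", "be"),
            ("observed", "VBN", "observe"), ("in", "IN"), ("some", "DT"),
            ("patients", "NNS", "patient"), (".", "."),
        ],
        [
            ("amod", 1, 0), ("nsubjpass", 3, 1), ("auxpass", 3, 2),
            ("prep", 3, 4), ("pobj", 4, 6), ("det", 6, 5), ("punct", 3, 7),
        ],
    )
    return {
        "sentences": [s1],
        "entities": [(0, 1, 2, "disorder")],
        "mentions": [],
        "links": [],
    }


ANAPHORA_CYCLE = {
    "PersonalPronoun": t_anaphora_personal,
    "PossessivePronoun": t_anaphora_possessive,
    "DefiniteNP": t_anaphora_definite,
    "DistributiveNP": t_anaphora_distributive_np,
    "DistributivePronoun": t_anaphora_distributive_pronoun,
    "ReciprocalPronoun": t_anaphora_reciprocal,
}
CATAPHORA_CYCLE = {
    "PersonalPronoun": t_cataphora_personal,
    "PossessivePronoun": t_cataphora_possessive,
    "DefiniteNP": t_cataphora_definite_list,
}
APPOSITIVE_CYCLE = {
    "DefiniteNP": t_appositive_definite,
    "IndefiniteNP": t_appositive_indefinite,
    "ZeroArticleNP": t_appositive_zero_article,
}
PREDNOM_CYCLE = {
    "IndefiniteNP": t_prednom_indefinite,
    "ZeroArticleNP": t_prednom_zero_article,
}

# subthreshold variants exist only for pronominal/definite anaphora; the
# other constructions are syntactically licensed and not threshold-driven
SUBTHRESHOLD_CYCLE = {
    "PersonalPronoun": t_anaphora_personal,
    "PossessivePronoun": t_anaphora_possessive,
    "DefiniteNP": t_anaphora_definite,
}

PRONOUN_ONLY = {MentionType.PersonalPronoun, MentionType.PossessivePronoun}


def _cycle(table: dict, restriction, count: int):
    if not count:
        return []
    names = [n for n in table if restriction is None or n in restriction]
    if not names:
        raise FixtureError("no template matches the requested mention types")
    return [table[names[i % len(names)]] for i in range(count)]


def generate(spec: FixtureSpec) -> GeneratedDocument:
    """Build one synthetic document realizing the spec's coreference mix."""
    if spec.mention_types and spec.appositive:
        bad = set(spec.mention_types) & {m.value for m in PRONOUN_ONLY}
        if bad and set(spec.mention_types) <= {m.value for m in PRONOUN_ONLY}:
            raise FixtureError(
                "appositive coreference cannot be expressed with pronoun mentions"
            )
    rng = random.Random(spec.seed)
    restriction = set(spec.mention_types) if spec.mention_types else None

    templates = []
    if spec.ambiguity == "subthreshold":
        templates += _cycle(SUBTHRESHOLD_CYCLE, restriction, spec.anaphora)
    elif spec.ambiguity == "tied":
        templates += [t_anaphora_personal] * spec.anaphora
    else:
        templates += _cycle(ANAPHORA_CYCLE, restriction, spec.anaphora)
    templates += _cycle(CATAPHORA_CYCLE, restriction, spec.cataphora) if spec.cataphora else []
    templates += [t_set_membership] * spec.set_membership
    templates += _cycle(APPOSITIVE_CYCLE, restriction, spec.appositive) if spec.appositive else []
    templates += _cycle(PREDNOM_CYCLE, restriction, spec.predicate_nominative) if spec.predicate_nominative else []

    instances = [t(rng, spec.ambiguity) for t in templates]
    instances += [t_distractor(rng, spec.ambiguity) for _ in range(spec.distractors)]
    if not instances:
        raise FixtureError("empty fixture spec")

    return _assemble(instances)


def _assemble(instances: list[dict]) -> GeneratedDocument:
    sentences: list[Sentence] = []
    text_parts: list[str] = []
    offset = 0
    entities: list[Entity] = []
    mentions: list[Mention] = []
    links: list[CoreferenceLink] = []

    def add_sentence(tokens_spec, edges):
        nonlocal offset
        toks = []
        pos = offset
        parts = []
        for i, raw in enumerate(tokens_spec):
            text, tag, lemma = _tok(raw)
            toks.append(Token(i, text, lemma, tag, Span(pos, pos + len(text))))
            parts.append(text)
            pos += len(text) + 1
        sent_text = " ".join(parts)
        g = DependencyGraph()
        for lab, gov, dep in edges:
            g.add(lab, gov, dep)
        sent = Sentence(
            index=len(sentences),
            span=Span(offset, offset + len(sent_text)),
            tokens=toks,
            graph=g,
        )
        sentences.append(sent)
        text_parts.append(sent_text)
        offset += len(sent_text) + 1
        return sent

    first = True
    for inst in instances:
        if not first:
            add_sentence(*SPACER)
        first = False
        local = [add_sentence(toks, edges) for toks, edges in inst["sentences"]]
        inst_entities = []
        for s, lo, hi, semtype in inst["entities"]:
            sent = local[s]
            span = Span(sent.tokens[lo].span.start, sent.tokens[hi - 1].span.end)
            ent = Entity(span=span, semtype=semtype)
            inst_entities.append(ent)
            entities.append(ent)
        inst_mentions = []
        for s, lo, hi, mtype in inst["mentions"]:
            sent = local[s]
            span = Span(sent.tokens[lo].span.start, sent.tokens[hi - 1].span.end)
            head = next(
                t.index
                for t in reversed(sent.tokens[lo:hi])
                if not t.is_punct()
            )
            m = Mention(span=span, mtype=mtype, head=(sent.index, head))
            inst_mentions.append(m)
            mentions.append(m)
        for ctype, m_idx, e_idxs in inst["links"]:
            for e_idx in e_idxs:
                links.append(
                    CoreferenceLink(
                        ctype=ctype,
                        mention=inst_mentions[m_idx],
                        referent=inst_entities[e_idx],
                    )
                )

    doc = Document(
        text="\n".join(text_parts), sentences=sentences, entities=list(entities)
    )
    doc.validate()

    chains = _links_to_chains(links)
    conllu = write_conllu(doc)
    ann = write_brat(doc.text, entities, mentions, links)
    return GeneratedDocument(
        doc=doc,
        entities=entities,
        mentions=mentions,
        links=links,
        chains=chains,
        conllu=conllu,
        brat_txt=doc.text,
        brat_ann=ann,
    )


def build_document(
    sentences,
    entities=(),
    mentions=(),
    links=(),
) -> GeneratedDocument:
    """Assemble one document from hand-written sentence templates.

    ``sentences`` is a list of ``(tokens, edges)`` pairs where tokens are
    ``(text, pos[, lemma])`` tuples and edges ``(label, governor, dependent)``
    token-index triples; entities/mentions/links use the same local
    coordinates as the generator templates.
    """
    return _assemble(
        [
            {
                "sentences": list(sentences),
                "entities": list(entities),
                "mentions": list(mentions),
                "links": list(links),
            }
        ]
    )


def _links_to_chains(links: list[CoreferenceLink]) -> list[Chain]:
    pools: list[list] = []
    index: dict = {}
    for l in links:
        pair = [l.mention, l.referent]
        found = sorted({index[p.span] for p in pair if p.span in index})
        if not found:
            pools.append([])
            tgt = len(pools) - 1
        else:
            tgt = found[0]
            for other in found[1:]:
                pools[tgt].extend(pools[other])
                pools[other] = []
        for p in pair:
            if all(p.span != q.span for q in pools[tgt]):
                pools[tgt].append(p)
        for p in pools[tgt]:
            index[p.span] = tgt
    return [
        Chain(members=sorted(p, key=lambda m: m.span.start))
        for p in pools
        if len(p) >= 2
    ]


def corpus_stats(generated: list[GeneratedDocument]) -> dict:
    """Counts of gold links per coreference type and of gold mentions per
    mention type across a generated corpus."""
    by_ctype: dict[str, int] = {}
    by_mtype: dict[str, int] = {}
    for g in generated:
        seen_pairs = set()
        for l in g.links:
            by_ctype[l.ctype.value] = by_ctype.get(l.ctype.value, 0) + 1
            seen_pairs.add((l.ctype, l.mention.span))
        for m in g.mentions:
            by_mtype[m.mtype.value] = by_mtype.get(m.mtype.value, 0) + 1
    return {"ctype": by_ctype, "mtype": by_mtype}
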