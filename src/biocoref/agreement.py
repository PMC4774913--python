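"""Agreement methods and the cumulative reward/penalty scoring function.

Each agreement method is a pure predicate over (mention, candidate,
document, lexical resources).  A scoring function is an ordered list of
``Method(reward,penalty)`` specifications; the compatibility score of a
candidate is the sum of rewards for agreements minus penalties for
disagreements, starting from zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .resources import (
    load_coercion_triggers,
    load_collective_nouns,
    load_connectives,
    load_gender_words,
    load_hypernyms,
)
from .stemmer import porter_stem
from .types import (
    ANIMATE_GROUPS,
    Conjunction,
    Document,
    Entity,
    Mention,
    MentionType,
    SemanticItem,
)

PLURAL_PRONOUNS = {
    "they", "them", "their", "theirs", "themselves",
    "we", "us", "our", "ours", "ourselves", "these", "those",
}
FIRST_PERSON = {"i", "me", "my", "mine", "myself", "we", "us", "our", "ours", "ourselves"}
SECOND_PERSON = {"you", "your", "yours", "yourself", "yourselves"}
MALE_PRONOUNS = {"he", "him", "his", "himself"}
FEMALE_PRONOUNS = {"she", "her", "hers", "herself"}
NEUTER_PRONOUNS = {"it", "its", "itself"}
MAYBE_ANIMATE_PRONOUNS = {"they", "them", "their", "theirs", "themselves"}
ANIMATE_WH = {"who", "whom", "whose"}
DETERMINER_POS = {"DT", "PDT", "PRP$"}
SKIP_POS_FOR_STEMS = {"DT", "PDT", "PRP", "PRP$", "IN", "TO", "CC"}
NOMINAL_POS = {"NN", "NNS", "NNP", "NNPS", "FW"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhiFeatures:
    number: str  # singular | plural
    gender: str  # Female | Male | Unknown
    animacy: str  # Animate | NotAnimate | MaybeAnimate
    person: str  # First | Second | Third


@dataclass(frozen=True)
class AgreementSpec:
    method: str
    reward: int
    penalty: int

    def __str__(self):
        return f"{self.method}({self.reward},{self.penalty})"


_SPEC_RE = re.compile(r"^\s*([A-Za-z]+)\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)\s*$")


def parse_agreement_spec(text: str) -> AgreementSpec:
    m = _SPEC_RE.match(text)
    if not m:
        raise ConfigError(f"cannot parse agreement spec {text!r}")
    name, rew, pen = m.groups()
    if name not in AGREEMENT_METHODS:
        raise ConfigError(f"unknown agreement method {name!r}")
    return AgreementSpec(name, int(rew), int(pen))


@dataclass(frozen=True)
class ScoredCandidate:
    candidate: object
    score: int


# --------------------------------------------------------------------- #
# phi features


def _is_pronoun_mention(item) -> bool:
    return isinstance(item, Mention) and item.mtype in (
        MentionType.PersonalPronoun,
        MentionType.PossessivePronoun,
        MentionType.DemonstrativePronoun,
        MentionType.RelativePronoun,
        MentionType.IndefinitePronoun,
        MentionType.DistributivePronoun,
        MentionType.ReciprocalPronoun,
    )


def compute_phi(item: SemanticItem, doc: Document) -> PhiFeatures:
    """Number / gender / animacy / person features of a mention or candidate.

    Total: returns the defaults (singular, Unknown, NotAnimate, Third)
    when nothing more specific applies.
    """
    if isinstance(item, Conjunction):
        animacy = "Animate" if item.semgroup in ANIMATE_GROUPS else "NotAnimate"
        return PhiFeatures("plural", "Unknown", animacy, "Third")

    ht = doc.head_token_of(item)
    head = ht[1] if ht else None
    text = doc.slice(item.span).lower()
    gender_words = load_gender_words()
    collectives = load_collective_nouns()

    if isinstance(item, Entity):
        number = "singular"
        if head is not None and head.pos in ("NNS", "NNPS"):
            number = "plural"
        if head is not None and head.lemma.lower() in collectives:
            number = "plural"
        gender = gender_words.get(head.lemma.lower(), "Unknown") if head else "Unknown"
        animacy = "Animate" if item.semgroup in ANIMATE_GROUPS else "NotAnimate"
        return PhiFeatures(number, gender, animacy, "Third")

    # mentions
    if _is_pronoun_mention(item):
        if item.mtype in (
            MentionType.ReciprocalPronoun,
            MentionType.DistributivePronoun,
        ):
            number = "plural"
        else:
            number = "plural" if text in PLURAL_PRONOUNS else "singular"
        if text in FIRST_PERSON:
            person = "First"
        elif text in SECOND_PERSON:
            person = "Second"
        else:
            person = "Third"
        if text in MALE_PRONOUNS:
            gender = "Male"
        elif text in FEMALE_PRONOUNS:
            gender = "Female"
        else:
            gender = "Unknown"
        if text in MALE_PRONOUNS | FEMALE_PRONOUNS or text in ANIMATE_WH:
            animacy = "Animate"
        elif text in NEUTER_PRONOUNS:
            animacy = "NotAnimate"
        elif text in MAYBE_ANIMATE_PRONOUNS or item.mtype in (
            MentionType.ReciprocalPronoun,
            MentionType.DistributivePronoun,
        ):
            animacy = "MaybeAnimate"
        elif text in FIRST_PERSON | SECOND_PERSON:
            animacy = "Animate"
        else:
            animacy = "MaybeAnimate" if text in ("these", "those") else "NotAnimate"
        return PhiFeatures(number, gender, animacy, person)

    # nominal mentions
    number = "singular"
    if head is not None and head.pos in ("NNS", "NNPS"):
        number = "plural"
    if head is not None and head.lemma.lower() in collectives:
        number = "plural"
    gender = gender_words.get(head.lemma.lower(), "Unknown") if head else "Unknown"
    semgroup = getattr(item, "semgroup", None)
    if semgroup in ANIMATE_GROUPS or (head and head.lemma.lower() in gender_words):
        animacy = "Animate"
    else:
        animacy = "NotAnimate"
    return PhiFeatures(number, gender, animacy, "Third")


# --------------------------------------------------------------------- #
# helpers


def _head_lemma(doc: Document, item) -> Optional[str]:
    ht = doc.head_token_of(item)
    return ht[1].lemma.lower() if ht else None


def _item_semgroup(item) -> Optional[str]:
    return getattr(item, "semgroup", None)


def _item_semtype(item) -> Optional[str]:
    if isinstance(item, Conjunction):
        types = {c.semtype for c in item.conjuncts}
        return types.pop() if len(types) == 1 else None
    return getattr(item, "semtype", None)


def _content_tokens(doc: Document, item):
    toks, _ = doc.align_span(item.span)
    return [t for t in toks if t.pos not in SKIP_POS_FOR_STEMS and not t.is_punct()]


def _premod_head_string(doc: Document, item) -> Optional[str]:
    toks, _ = doc.align_span(item.span)
    ht = doc.head_token_of(item)
    if ht is None:
        return None
    head = ht[1]
    kept = [t for t in toks if t.span.end <= head.span.end]
    while kept and kept[0].pos in DETERMINER_POS | {"PRP"}:
        kept = kept[1:]
    if not kept:
        return None
    return " ".join(t.text.lower() for t in kept)


def _only_between(doc: Document, a, b, allowed) -> bool:
    lo, hi = sorted([a.span, b.span], key=lambda s: s.start)
    if lo.end > hi.start:
        return False
    sent = doc.sentence_of(lo)
    if sent is None or doc.sentence_of(hi) is not sent:
        return False
    between = [
        t for t in sent.tokens if lo.end <= t.span.start and t.span.end <= hi.start
    ]
    return all(allowed(t) for t in between)


# --------------------------------------------------------------------- #
# agreement methods


def _agree_number(mention, cand, doc, res):
    text = doc.slice(mention.span).lower()
    two_like = (
        isinstance(mention, Mention)
        and mention.mtype
        in (MentionType.ReciprocalPronoun, MentionType.DistributivePronoun)
    ) or re.search(r"\btwo\b", text)
    if two_like:
        return isinstance(cand, Conjunction) and len(cand.conjuncts) == 2
    return compute_phi(mention, doc).number == compute_phi(cand, doc).number


def _agree_person(mention, cand, doc, res):
    return compute_phi(mention, doc).person == compute_phi(cand, doc).person


def _agree_gender(mention, cand, doc, res):
    return compute_phi(mention, doc).gender == compute_phi(cand, doc).gender


def _agree_animacy(mention, cand, doc, res):
    a, b = compute_phi(mention, doc).animacy, compute_phi(cand, doc).animacy
    return a == b or "MaybeAnimate" in (a, b)


def _agree_hypernym(mention, cand, doc, res):
    lemma = _head_lemma(doc, mention)
    if lemma is None:
        return False
    ht = doc.head_token_of(mention)
    surface = doc.slice(ht[1].span).lower() if ht else None
    group = _item_semgroup(cand)
    semtype = _item_semtype(cand)
    hyp = res.get("hypernyms") or load_hypernyms()
    for key in (group, semtype):
        words = hyp.get(key, frozenset()) if key else frozenset()
        if lemma in words or (surface and surface in words):
            return True
    return False


def _agree_connective(mention, cand, doc, res):
    sent = doc.sentence_of(mention.span)
    if sent is None:
        return False
    text = doc.slice(sent.span).lower()
    connectives = res.get("connectives") or load_connectives()
    return any(text.startswith(c) for c in connectives)


def _appositive_pair(doc, a_item, b_item) -> bool:
    a = doc.head_token_of(a_item)
    b = doc.head_token_of(b_item)
    if a and b and a[0] is b[0]:
        sent = a[0]
        ai, bi = a[1].index, b[1].index
        for e in sent.graph:
            if e.label in ("appos", "abbrev") and {e.governor, e.dependent} == {
                ai,
                bi,
            }:
                return True
    # contiguous noun phrases as appositives
    return _only_between(doc, a_item, b_item, lambda t: t.is_punct())


def _agree_appositive(mention, cand, doc, res):
    cands = cand.conjuncts if isinstance(cand, Conjunction) else [cand]
    return any(_appositive_pair(doc, mention, c) for c in cands)


def _agree_pred_nominative(mention, cand, doc, res):
    ht = doc.head_token_of(mention)
    if ht is None:
        return False
    sent, head = ht
    if not sent.graph.dependents(head.index, {"cop"}):
        return False
    if sent.graph.dependents(head.index, {"neg"}):
        return False
    subj = {
        e.dependent
        for e in sent.graph.dependents(head.index, {"nsubj", "nsubjpass"})
    }
    cands = cand.conjuncts if isinstance(cand, Conjunction) else [cand]
    for c in cands:
        ct = doc.head_token_of(c)
        if ct and ct[0] is sent and ct[1].index in subj:
            return True
    return False


def _agree_exact_string(mention, cand, doc, res):
    return doc.slice(mention.span).lower() == doc.slice(cand.span).lower()


def _agree_headword(mention, cand, doc, res):
    a, b = _head_lemma(doc, mention), _head_lemma(doc, cand)
    return a is not None and a == b


def _agree_premod_head(mention, cand, doc, res):
    a = _premod_head_string(doc, mention)
    b = _premod_head_string(doc, cand)
    return a is not None and a == b


def _numeric_tokens(tokens):
    return {t.text for t in tokens if any(ch.isdigit() for ch in t.text)}


def relaxed_stem_overlap(doc: Document, mention, cand) -> float:
    """Stem overlap ratio |shared| / max(|A|, |B|) over content-word stems."""
    a_toks = _content_tokens(doc, mention)
    b_toks = _content_tokens(doc, cand)
    a = {porter_stem(t.text) for t in a_toks}
    b = {porter_stem(t.text) for t in b_toks}
    if not a or not b:
        return 0.0
    return len(a & b) / max(len(a), len(b))


def _agree_relaxed_stem(mention, cand, doc, res):
    a_toks = _content_tokens(doc, mention)
    b_toks = _content_tokens(doc, cand)
    if _numeric_tokens(a_toks) != _numeric_tokens(b_toks):
        return False
    return relaxed_stem_overlap(doc, mention, cand) > 0.5


def _agree_key_value(mention, cand, doc, res):
    t_m, t_c = _item_semtype(mention), _item_semtype(cand)
    if t_m is None or t_c is None or t_m != t_c:
        return False
    lo, hi = sorted([mention.span, cand.span], key=lambda s: s.start)
    if lo.end > hi.start:
        return False
    gap = doc.text[lo.end : hi.start]
    return ":" in gap and all(ch in ": \t" for ch in gap)


def _coerced_groups(mention, doc, res):
    """Semantic groups a possessive pronoun is coerced to by the headword of
    the noun phrase it modifies."""
    ht = doc.head_token_of(mention)
    if ht is None:
        return set()
    sent, tok = ht
    headwords = []
    for e in sent.graph.governors(tok.index, {"poss"}):
        headwords.append(sent.tokens[e.governor])
    if not headwords and tok.index + 1 < len(sent.tokens):
        nxt = sent.tokens[tok.index + 1]
        if nxt.pos in NOMINAL_POS:
            headwords.append(nxt)
        elif tok.index + 2 < len(sent.tokens) and sent.tokens[tok.index + 2].pos in NOMINAL_POS:
            # allow one intervening modifier: "its beta1-selectivity"
            headwords.append(sent.tokens[tok.index + 2])
    triggers = res.get("coercion") or load_coercion_triggers()
    groups = set()
    for hw in headwords:
        for group, words in triggers.items():
            if hw.lemma.lower() in words or hw.text.lower() in words:
                groups.add(group)
    return groups


def _agree_coercion(mention, cand, doc, res):
    groups = _coerced_groups(mention, doc, res)
    return bool(groups) and _item_semgroup(cand) in groups


def _agree_semtype(mention, cand, doc, res):
    a, b = _item_semtype(mention), _item_semtype(cand)
    return a is not None and a == b


def _agree_semgroup(mention, cand, doc, res):
    a, b = _item_semgroup(mention), _item_semgroup(cand)
    return a is not None and a == b


def _agree_taxonomy(mention, cand, doc, res):
    taxonomy = res.get("taxonomy")
    if taxonomy is None:
        raise ConfigError("Taxonomy agreement requires a taxonomy provider")
    a = getattr(mention, "concept", None)
    b = getattr(cand, "concept", None)
    if isinstance(cand, Conjunction):
        return any(
            _agree_taxonomy(mention, c, doc, res) for c in cand.conjuncts
        )
    return bool(a and b) and taxonomy.is_ancestor(a, b)


def _agree_adjacency(mention, cand, doc, res):
    return _only_between(
        doc, mention, cand, lambda t: t.is_punct() or t.pos in ("IN", "TO")
    )


AGREEMENT_METHODS = {
    "Number": _agree_number,
    "Person": _agree_person,
    "Gender": _agree_gender,
    "Animacy": _agree_animacy,
    "HypernymList": _agree_hypernym,
    "DiscourseConnective": _agree_connective,
    "SyntacticAppositive": _agree_appositive,
    "SyntacticPredicateNominative": _agree_pred_nominative,
    "ExactString": _agree_exact_string,
    "HeadWord": _agree_headword,
    "PreModifierAndHead": _agree_premod_head,
    "RelaxedStem": _agree_relaxed_stem,
    "KeyValuePair": _agree_key_value,
    "SemanticCoercion": _agree_coercion,
    "SemanticType": _agree_semtype,
    "SemanticGroup": _agree_semgroup,
    "Taxonomy": _agree_taxonomy,
    "Adjacency": _agree_adjacency,
}


def agree(
    method: str,
    mention,
    cand,
    doc: Document,
    resources: Optional[dict] = None,
) -> bool:
    """Evaluate one agreement method as a boolean predicate."""
    fn = AGREEMENT_METHODS.get(method)
    if fn is None:
        raise ConfigError(f"unknown agreement method {method!r}")
    return bool(fn(mention, cand, doc, resources or {}))


def score_candidate(
    mention,
    cand,
    specs: list[AgreementSpec],
    doc: Document,
    resources: Optional[dict] = None,
) -> ScoredCandidate:
    """Cumulative compatibility score: +reward on agreement, -penalty
    otherwise, starting from zero."""
    if not specs:
        raise ConfigError("scoring function must list at least one method")
    score = 0
    for spec in specs:
        if agree(spec.method, mention, cand, doc, resources):
            score += spec.reward
        else:
            score -= spec.penalty
    return ScoredCandidate(cand, score)
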