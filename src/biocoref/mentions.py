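"""Coreferential mention detection and mention filtering.

Pronoun mentions are detected from tokens (POS tags, token lists and the
dependency relations they occur in); nominal mentions from the NP chunks
produced by the NP-internal transformation, typed by their initial
determiner, with zero-article noun phrases additionally required to have
a hypernym headword for some semantic group.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .preprocessing import ConfigError
from .resources import load_hypernyms
from .types import (
    CLAUSAL_COMPLEMENT_LABELS,
    Document,
    DependencyGraph,
    Mention,
    MentionType,
    Sentence,
    Span,
    Token,
)

DEMONSTRATIVES = {"this", "that", "these", "those"}
DISTRIBUTIVES = {"both", "either", "neither", "each"}
INDEFINITE_PRONOUNS = {"another", "some", "all"}
INDEFINITE_DETERMINERS = {"a", "an", "any", "some", "all", "another", "other"}
RECIPROCALS = (("each", "other"), ("one", "another"))
RELATIVE_POS = {"WDT", "WRB", "WP", "WP$"}
REFLEXIVES = {
    "itself",
    "themselves",
    "himself",
    "herself",
    "myself",
    "yourself",
    "ourselves",
    "yourselves",
    "oneself",
}
FIRST_SECOND_PERSON = {
    "i", "me", "we", "us", "my", "mine", "our", "ours", "myself", "ourselves",
    "you", "your", "yours", "yourself", "yourselves",
}
NOMINAL_POS = {"NN", "NNS", "NNP", "NNPS", "FW"}
NON_RELATIVE_WH = {"how", "what", "why", "whatever", "however"}


def is_pleonastic_it(
    token: Token, graph: DependencyGraph, strict_negated_rule: bool = False
) -> bool:
    """Detect non-referential *it* from its dependency configuration.

    Default reading: *it* is pleonastic when it is the (passive) subject of
    a governor that also takes a clausal complement (infmod/ccomp/xcomp/
    vmod), as in "It is not certain that ...".  The alternative
    ``strict_negated_rule`` treats *it* as pleonastic when the governor has
    any other dependent outside that label set.
    """
    if token.text.lower() != "it":
        return False
    for e in graph.governors(token.index, {"nsubj", "nsubjpass"}):
        x = e.governor
        others = [d for d in graph.dependents(x) if d.dependent != token.index]
        if strict_negated_rule:
            if any(d.label not in CLAUSAL_COMPLEMENT_LABELS for d in others):
                return True
        else:
            if any(d.label in CLAUSAL_COMPLEMENT_LABELS for d in others):
                return True
    return False


def _in_determiner_position(sent: Sentence, tok: Token) -> bool:
    if sent.graph.governors(tok.index, {"det", "predet"}):
        return True
    # NP reading preferred when an unspecific attachment leaves the
    # determiner status open but a nominal token follows
    nxt = tok.index + 1
    return nxt < len(sent.tokens) and sent.tokens[nxt].pos in NOMINAL_POS


def _reciprocal_spans(sent: Sentence) -> list[tuple[Span, int]]:
    out = []
    for a, b in zip(sent.tokens, sent.tokens[1:]):
        for w1, w2 in RECIPROCALS:
            if a.text.lower() == w1 and b.text.lower() == w2:
                out.append((Span(a.span.start, b.span.end), b.index))
    return out


def detect_mentions(
    doc: Document,
    allowed: Optional[set[MentionType]] = None,
    hypernyms: Optional[dict] = None,
) -> list[Mention]:
    """Annotate every token/NP chunk satisfying a mention-type rule.

    Output is unique per (span, mention type); ``allowed`` restricts the
    types produced.
    """
    if allowed is not None and MentionType.ZeroArticleNP in allowed:
        hyp = hypernyms if hypernyms is not None else load_hypernyms()
        if not hyp:
            raise ConfigError("ZeroArticleNP detection requires hypernym lists")
    hyp = hypernyms if hypernyms is not None else load_hypernyms()

    found: list[Mention] = []

    def want(mtype: MentionType) -> bool:
        return allowed is None or mtype in allowed

    def add(m: Mention):
        if m not in found:
            found.append(m)

    for sent in doc.sentences:
        recips = _reciprocal_spans(sent)
        recip_tokens = set()
        for span, head in recips:
            toks, _ = doc.align_span(span)
            recip_tokens.update(t.index for t in toks)
            if want(MentionType.ReciprocalPronoun):
                add(
                    Mention(
                        span=span,
                        mtype=MentionType.ReciprocalPronoun,
                        head=(sent.index, head),
                    )
                )

        for tok in sent.tokens:
            low = tok.text.lower()
            if tok.index in recip_tokens:
                continue
            if tok.pos == "PRP" and want(MentionType.PersonalPronoun):
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.PersonalPronoun,
                        head=(sent.index, tok.index),
                        reflexive=low in REFLEXIVES,
                    )
                )
            elif tok.pos == "PRP$" and want(MentionType.PossessivePronoun):
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.PossessivePronoun,
                        head=(sent.index, tok.index),
                    )
                )
            elif (
                low in DEMONSTRATIVES
                and want(MentionType.DemonstrativePronoun)
                and not _in_determiner_position(sent, tok)
                and not (low == "that" and _is_complementizer(sent, tok))
            ):
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.DemonstrativePronoun,
                        head=(sent.index, tok.index),
                    )
                )
            elif (
                low in DISTRIBUTIVES
                and want(MentionType.DistributivePronoun)
                and not sent.graph.governors(tok.index, {"preconj"})
                and not sent.graph.dependents(tok.index, {"pobj"})
                and not _in_determiner_position(sent, tok)
            ):
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.DistributivePronoun,
                        head=(sent.index, tok.index),
                    )
                )
            elif (
                tok.pos in RELATIVE_POS
                or (low == "that" and tok.pos == "IN")
            ) and want(MentionType.RelativePronoun):
                if low == "that" and _is_complementizer(sent, tok):
                    continue
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.RelativePronoun,
                        head=(sent.index, tok.index),
                    )
                )
            elif (
                low in INDEFINITE_PRONOUNS
                and tok.pos == "DT"
                and want(MentionType.IndefinitePronoun)
                and not _in_determiner_position(sent, tok)
            ):
                add(
                    Mention(
                        span=tok.span,
                        mtype=MentionType.IndefinitePronoun,
                        head=(sent.index, tok.index),
                    )
                )

        for span, head_idx in sent.chunks:
            toks, _ = doc.align_span(span)
            first = toks[0]
            low = first.text.lower()
            head_tok = sent.tokens[head_idx]
            kwargs = dict(head=(sent.index, head_idx))
            if low == "the" and want(MentionType.DefiniteNP):
                add(Mention(span=span, mtype=MentionType.DefiniteNP, **kwargs))
            elif (low in DEMONSTRATIVES or low == "such") and want(
                MentionType.DemonstrativeNP
            ):
                if len(toks) > 1:
                    add(
                        Mention(
                            span=span, mtype=MentionType.DemonstrativeNP, **kwargs
                        )
                    )
            elif low in DISTRIBUTIVES and want(MentionType.DistributiveNP):
                if len(toks) > 1:
                    add(
                        Mention(
                            span=span, mtype=MentionType.DistributiveNP, **kwargs
                        )
                    )
            elif low in INDEFINITE_DETERMINERS and want(MentionType.IndefiniteNP):
                if len(toks) > 1:
                    add(Mention(span=span, mtype=MentionType.IndefiniteNP, **kwargs))
            elif (
                first.pos not in ("DT", "PDT", "PRP$")
                and want(MentionType.ZeroArticleNP)
            ):
                lemma = head_tok.lemma.lower()
                for group, words in hyp.items():
                    if lemma in words or head_tok.text.lower() in words:
                        add(
                            Mention(
                                span=span,
                                mtype=MentionType.ZeroArticleNP,
                                semgroup=group,
                                **kwargs,
                            )
                        )
                        break
    found.sort(key=lambda m: (m.span.start, m.span.end))
    compute_mention_flags(found, doc)
    return found


def _is_complementizer(sent: Sentence, tok: Token) -> bool:
    if sent.graph.governors(tok.index, {"mark", "complm"}):
        return True
    return tok.pos == "IN" and not sent.graph.governors(
        tok.index, {"rcmod", "ref", "nsubj", "nsubjpass", "dobj"}
    ) and not _heads_relative_clause(sent, tok)


def _heads_relative_clause(sent: Sentence, tok: Token) -> bool:
    # "that" acting as a relative marker is a dependent inside an rcmod clause
    for e in sent.graph.governors(tok.index):
        if sent.graph.governors(e.governor, {"rcmod"}):
            return True
    return False


# --------------------------------------------------------------------- #
# flags and mention filters


def compute_mention_flags(mentions: Sequence[Mention], doc: Document) -> None:
    """Populate rigid_designator and in_appositive flags on nominal mentions."""
    entity_strings = {doc.slice(e.span).lower() for e in doc.entities}
    for m in mentions:
        ht = doc.head_token_of(m)
        if ht is None:
            continue
        sent, head = ht
        inside_entity = any(
            e.span.contains(head.span) for e in doc.entities
        )
        bare = _strip_determiner(doc, m).lower()
        m.rigid_designator = inside_entity or (
            bool(bare) and bare in entity_strings
        )
        m.in_appositive = _in_appositive(m, sent, head, doc)


def _strip_determiner(doc: Document, m: Mention) -> str:
    toks, _ = doc.align_span(m.span)
    if toks and toks[0].pos in ("DT", "PDT", "PRP$"):
        toks = toks[1:]
    if not toks:
        return ""
    return doc.text[toks[0].span.start : toks[-1].span.end]


def _in_appositive(m: Mention, sent, head, doc: Document) -> bool:
    for e in sent.graph.governors(head.index, {"appos", "abbrev"}):
        return True
    for e in sent.graph.dependents(head.index, {"appos", "abbrev"}):
        return True
    # contiguous-NP appositive: an entity directly adjacent to the mention
    # with at most punctuation between
    for ent in doc.entities:
        if doc.sentence_of(ent.span) is not sent:
            continue
        if ent.span.overlaps(m.span):
            continue
        lo, hi = sorted([m.span, ent.span], key=lambda s: s.start)
        between = [
            t
            for t in sent.tokens
            if lo.end <= t.span.start and t.span.end <= hi.start
        ]
        gap = doc.text[lo.end : hi.start]
        if all(t.is_punct() for t in between) and not any(
            ch.isalnum() for ch in gap
        ):
            return True
    return False


def _document_initial(m: Mention, doc: Document) -> bool:
    return not doc.text[: m.span.start].strip()


def _has_word_following(m: Mention, doc: Document) -> bool:
    return "following" in doc.slice(m.span).lower().split()


PRONOUN_TYPES_FOR_THIRD = {
    MentionType.PersonalPronoun,
    MentionType.PossessivePronoun,
}


def apply_mention_filters(
    mentions: Sequence[Mention],
    filters: Iterable[str],
    doc: Document,
    strict_negated_rule: bool = False,
) -> list[Mention]:
    """Keep mentions passing every named filter (filters are conjunctive
    predicates, hence order-independent)."""
    out = list(mentions)
    for name in filters:
        if name == "ThirdPerson":
            out = [
                m
                for m in out
                if m.mtype not in PRONOUN_TYPES_FOR_THIRD
                or doc.slice(m.span).lower() not in FIRST_SECOND_PERSON
            ]
        elif name == "PleonasticIt":
            kept = []
            for m in out:
                if m.mtype is MentionType.PersonalPronoun:
                    ht = doc.head_token_of(m)
                    if ht and is_pleonastic_it(
                        ht[1], ht[0].graph, strict_negated_rule
                    ):
                        m.pleonastic = True
                        continue
                kept.append(m)
            out = kept
        elif name == "Anaphoricity":
            out = [
                m
                for m in out
                if m.mtype in PRONOUN_TYPES_FOR_THIRD
                or not (
                    m.rigid_designator
                    or m.in_appositive
                    or _has_word_following(m, doc)
                    or _document_initial(m, doc)
                )
            ]
        elif name == "Cataphoricity":
            out = [
                m
                for m in out
                if not (m.rigid_designator or m.in_appositive)
                and (_has_word_following(m, doc) or _document_initial(m, doc))
            ]
        elif name == "CoreferentialPronoun":
            out = [
                m
                for m in out
                if m.mtype is not MentionType.RelativePronoun
                or doc.slice(m.span).lower() not in NON_RELATIVE_WH
            ]
        else:
            raise ConfigError(f"unknown mention filter {name!r}")
    return out


# --------------------------------------------------------------------- #
# gold-mention typing (cluster-annotated corpora)

_KEYWORD_TYPES = [
    ({"which", "who", "whom", "whose", "that"}, MentionType.RelativePronoun),
    ({"the"}, MentionType.DefiniteNP),
    ({"this", "these", "those", "such"}, MentionType.DemonstrativeNP),
    ({"a", "an", "any", "another", "other"}, MentionType.IndefiniteNP),
    ({"both", "each", "either", "neither"}, MentionType.DistributiveNP),
]


def type_gold_mentions(
    gold_spans: Sequence[Span], doc: Document, semtypes: Optional[Sequence[str]] = None
) -> list[Mention]:
    """Assign mention types to externally supplied gold spans.

    The detection machinery is consulted first; keyword heuristics second;
    the default is a zero-article noun phrase.
    """
    detected = {m.span: m for m in detect_mentions(doc)}
    out = []
    for i, span in enumerate(gold_spans):
        toks, _ = doc.align_span(span)  # raises when not alignable
        semtype = semtypes[i] if semtypes else None
        if span in detected:
            m = detected[span]
            m.semtype = semtype or m.semtype
            out.append(m)
            continue
        first = toks[0].text.lower()
        mtype = None
        if len(toks) == 1:
            if toks[0].pos == "PRP":
                mtype = MentionType.PersonalPronoun
            elif toks[0].pos == "PRP$":
                mtype = MentionType.PossessivePronoun
        if mtype is None:
            for words, t in _KEYWORD_TYPES:
                if first in words:
                    mtype = t
                    break
        if mtype is None and toks[0].pos == "PRP$":
            mtype = MentionType.DefiniteNP  # possessive-determined nominal
        if mtype is None:
            mtype = MentionType.ZeroArticleNP
        head = toks[-1]
        if mtype is MentionType.RelativePronoun:
            head = toks[0]
        sent = doc.sentence_of(span)
        out.append(
            Mention(
                span=span,
                mtype=mtype,
                head=(sent.index, head.index) if sent else None,
                semtype=semtype,
            )
        )
    compute_mention_flags(out, doc)
    return out
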