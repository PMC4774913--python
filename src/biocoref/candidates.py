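"""Candidate-referent selection: build the candidate pool for a mention and
apply the strategy's candidate filters sequentially."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .resources import load_exemplification_triggers
from .types import (
    APPOSITIVE_LABELS,
    COORD_LABELS,
    OBJECT_LABELS,
    PREP_LABELS,
    SUBJECT_LABELS,
    Conjunction,
    Document,
    Entity,
    Mention,
    Span,
)

NOMINAL_POS = {"NN", "NNS", "NNP", "NNPS", "FW"}

VERB_POS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VerbHead:
    """A verb-phrase head usable as a candidate under the VerbPhrase filter."""

    span: Span
    sentence: int
    token: int


def item_class(item) -> str:
    if isinstance(item, VerbHead):
        return "verb"
    if isinstance(item, Conjunction):
        return "conjunction"
    if isinstance(item, Entity):
        return "entity"
    if isinstance(item, Mention):
        return "mention"
    raise TypeError(type(item))


@dataclass(frozen=True)
class CandidateFilterSpec:
    name: str
    parameter: Optional[Union[int, str, tuple]] = None


def _precedes(cand_span: Span, mention_span: Span) -> bool:
    """Span order for prior/subsequent discourse; a container precedes its
    content."""
    if cand_span.start != mention_span.start:
        return cand_span.start < mention_span.start
    return cand_span.end > mention_span.end


def build_pool(mention: Mention, doc: Document) -> list:
    """Initial candidate pool: entities, conjunctions, discourse conjunct
    sets, other coreferential mentions, and verb heads."""
    pool: list = []
    pool.extend(doc.entities)
    pool.extend(doc.conjunctions)
    pool.extend(doc.discourse_sets)
    for m in doc.mentions:
        if m.span.overlaps(mention.span):
            continue
        # a mention whose head token sits inside an entity annotation is an
        # occurrence of that entity; the entity itself already stands in the
        # pool, so the duplicate is skipped
        ht = doc.head_token_of(m)
        if ht is not None and any(
            e.span.contains(ht[1].span) for e in doc.entities
        ):
            continue
        pool.append(m)
    for sent in doc.sentences:
        for t in sent.tokens:
            if t.pos in VERB_POS:
                pool.append(VerbHead(t.span, sent.index, t.index))
    return pool


def _window_keep(item, mention: Mention, doc: Document, parameter) -> bool:
    m_sent = doc.sentence_index_of(mention.span)
    if parameter == "Document":
        return True
    if parameter == "Section":
        for sec in doc.sections or []:
            if sec.span.start <= mention.span.start < sec.span.end:
                return sec.span.start <= item.span.start < sec.span.end
        return True
    if parameter == "Sentence":
        k = 1
    else:
        k = int(parameter)
    i_sent = doc.sentence_index_of(item.span)
    return abs(i_sent - m_sent) <= k - 1


def syntactic_configuration_excludes(
    mention: Mention, cand, doc: Document
) -> bool:
    """Modified i-within-i filter over the dependency path between mention
    and candidate.  Cross-sentence pairs (no path) are never excluded."""
    m = doc.head_token_of(mention)
    c = doc.head_token_of(cand) if not isinstance(cand, VerbHead) else None
    if isinstance(cand, VerbHead):
        c = (doc.sentences[cand.sentence], doc.sentences[cand.sentence].tokens[cand.token])
    if m is None or c is None:
        return False
    m_sent, m_tok = m
    c_sent, c_tok = c
    if m_sent is not c_sent:
        return False
    graph = m_sent.graph
    path = graph.path(m_tok.index, c_tok.index)
    if path is None:
        return False

    # (a) subject and object of the same verb
    for v in range(len(m_sent.tokens)):
        if m_sent.tokens[v].pos not in VERB_POS:
            continue
        subj = {e.dependent for e in graph.dependents(v, SUBJECT_LABELS)}
        obj = {e.dependent for e in graph.dependents(v, OBJECT_LABELS)}
        pair = {m_tok.index, c_tok.index}
        if pair & subj and pair & obj and len(pair) == 2:
            return True
    # (b) subject and object of a nominal predicate (copular construction)
    for n_tok in m_sent.tokens:
        if n_tok.pos not in NOMINAL_POS:
            continue
        if not graph.dependents(n_tok.index, {"cop"}):
            continue
        subj = {e.dependent for e in graph.dependents(n_tok.index, SUBJECT_LABELS)}
        pair = {m_tok.index, c_tok.index}
        if n_tok.index in pair and (pair - {n_tok.index}) & subj:
            return True
    if len(path) <= 2:
        # (c) appositive-indicating edge on a short path
        if any(e.label in APPOSITIVE_LABELS for e in path):
            return True
        # (d) all non-appositive edges indicate subject/object/prepositional/
        #     coordination constructions
        construction = SUBJECT_LABELS | OBJECT_LABELS | PREP_LABELS | COORD_LABELS
        rest = [e for e in path if e.label not in APPOSITIVE_LABELS]
        if rest and all(e.label in construction for e in rest):
            return True
    return False


def _parenthetical_spans(doc: Document) -> list[Span]:
    spans = []
    stack = []
    for i, ch in enumerate(doc.text):
        if ch in "([":
            stack.append(i)
        elif ch in ")]" and stack:
            spans.append(Span(stack.pop(), i + 1))
    return spans


def is_exemplification(cand, doc: Document) -> bool:
    """True when the candidate instantiates a broader class mentioned in the
    same sentence: it sits in a parenthetical, or follows an exemplification
    trigger phrase (e.g., such as, including), in either case preceded by a
    nominal expression."""
    if isinstance(cand, VerbHead):
        return False
    sent = doc.sentence_of(cand.span)
    if sent is None:
        return False

    def preceded_by_nominal(pos: int) -> bool:
        prev = [
            t
            for t in sent.tokens
            if t.span.end <= pos and not t.is_punct()
        ]
        return bool(prev) and prev[-1].pos in NOMINAL_POS

    for pspan in _parenthetical_spans(doc):
        if pspan.contains(cand.span) and sent.span.contains(pspan):
            if preceded_by_nominal(pspan.start):
                return True
    sent_text = doc.slice(sent.span).lower()
    for trig in load_exemplification_triggers():
        start = 0
        while True:
            i = sent_text.find(trig, start)
            if i < 0:
                break
            abs_pos = sent.span.start + i
            boundary_ok = (i == 0 or not sent_text[i - 1].isalnum()) and (
                i + len(trig) >= len(sent_text)
                or not sent_text[i + len(trig)].isalnum()
            )
            if (
                boundary_ok
                and abs_pos < cand.span.start
                and preceded_by_nominal(abs_pos)
            ):
                # the exemplifying phrase ends at the first verb or closing
                # bracket after the trigger
                scope_end = sent.span.end
                for t in sent.tokens:
                    if t.span.start > abs_pos and (
                        t.pos in VERB_POS or t.text in ")]"
                    ):
                        scope_end = t.span.start
                        break
                if cand.span.end <= scope_end:
                    return True
            start = i + 1
    return False


def apply_filter(
    spec: CandidateFilterSpec, pool: list, mention: Mention, doc: Document
) -> list:
    name = spec.name
    if name == "PriorDiscourse":
        return [c for c in pool if _precedes(c.span, mention.span)]
    if name == "SubsequentDiscourse":
        return [
            c
            for c in pool
            if c.span != mention.span and not _precedes(c.span, mention.span)
        ]
    if name == "WindowSize":
        if spec.parameter is None:
            raise ConfigError("WindowSize requires a parameter")
        return [c for c in pool if _window_keep(c, mention, doc, spec.parameter)]
    if name in ("SyntacticConfiguration", "SyntacticConfig"):
        return [
            c for c in pool if not syntactic_configuration_excludes(mention, c, doc)
        ]
    if name == "NounPhrase":
        return [c for c in pool if item_class(c) != "verb"]
    if name == "VerbPhrase":
        return [c for c in pool if item_class(c) == "verb"]
    if name == "SemanticClass":
        classes = spec.parameter or ("entity", "mention", "conjunction")
        return [c for c in pool if item_class(c) in classes]
    if name == "Default":
        # noun phrases of the allowed semantic classes, verb heads excluded
        return [
            c
            for c in pool
            if item_class(c) in ("entity", "mention", "conjunction")
        ]
    if name == "Exemplification":
        return [c for c in pool if not is_exemplification(c, doc)]
    raise ConfigError(f"unknown candidate filter {name!r}")


def generate_candidates(
    mention: Mention,
    doc: Document,
    filters: Sequence[CandidateFilterSpec],
) -> list:
    """Sequentially filter the initial pool down to the candidate set."""
    if not filters:
        raise ConfigError("at least one candidate filter is required")
    pool = build_pool(mention, doc)
    for spec in filters:
        pool = apply_filter(spec, pool, mention, doc)
    return pool
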