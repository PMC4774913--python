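"""Pre-resolution document processing.

Implements the ordered dependency-graph transformations (semantic
enrichment, PP-attachment correction, modifier/term/plain coordination,
NP-internal chunking), recognition of semantically compatible coordinated
entities, section segmentation for drug labels and discharge summaries,
and discourse-level itemized-list recognition.
"""

from __future__ import annotations

import re
from typing import Optional

from .resources import load_pp_affinities, load_spl_headers
from .types import (
    Conjunction,
    DependencyEdge,
    Document,
    Entity,
    Section,
    Sentence,
    Span,
)

MODIFIER_LABELS = {"det", "amod", "nn", "num", "poss", "predet", "quantmod"}
NOMINAL_POS = {"NN", "NNS", "NNP", "NNPS", "FW"}
VERB_POS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD"}


class ConfigError(ValueError):
    pass


# --------------------------------------------------------------------- #
# transformations


def _entity_token_indices(doc: Document, sent: Sentence, ent: Entity) -> list[int]:
    return [t.index for t in sent.tokens if t.span.overlaps(ent.span)]


def _entity_head_index(doc: Document, sent: Sentence, ent: Entity) -> int:
    idxs = [
        t.index
        for t in sent.tokens
        if t.span.overlaps(ent.span) and not t.is_punct()
    ]
    if not idxs:
        idxs = _entity_token_indices(doc, sent, ent)
    return idxs[-1]


def semantic_enrichment(doc: Document) -> None:
    """Collapse each multi-token entity onto its head token.

    Intra-entity dependencies are deleted and edges crossing the entity
    boundary are re-pointed to the head token, yielding the simplified
    graph in which an entity is a single node.
    """
    for ent in doc.entities:
        sent = doc.sentence_of(ent.span)
        if sent is None:
            continue
        idxs = set(_entity_token_indices(doc, sent, ent))
        if len(idxs) < 2:
            continue
        head = _entity_head_index(doc, sent, ent)
        new_edges = []
        for e in sent.graph:
            gin, din = e.governor in idxs, e.dependent in idxs
            if gin and din:
                continue  # intra-entity edge deleted
            gov = head if gin else e.governor
            dep = head if din else e.dependent
            edge = DependencyEdge(e.label, gov, dep)
            if edge not in new_edges:
                new_edges.append(edge)
        sent.graph.replace(new_edges)


def pp_attachment_correction(doc: Document) -> None:
    """Re-attach verb-attached prepositions to an immediately preceding
    noun when a configured (noun, preposition) affinity pair licenses it."""
    affinities = load_pp_affinities()
    for sent in doc.sentences:
        new_edges = []
        for e in sent.graph:
            if e.label == "prep" and sent.tokens[e.governor].pos in VERB_POS:
                p = sent.tokens[e.dependent]
                j = e.dependent - 1
                while j >= 0 and sent.tokens[j].is_punct():
                    j -= 1
                if j >= 0 and sent.tokens[j].pos in NOMINAL_POS:
                    noun = sent.tokens[j]
                    if (noun.lemma.lower(), p.text.lower()) in affinities:
                        new_edges.append(DependencyEdge("prep", noun.index, p.index))
                        continue
            new_edges.append(e)
        sent.graph.replace(new_edges)


def _is_entity_head(doc: Document, sent: Sentence, idx: int) -> Optional[Entity]:
    for ent in doc.entities:
        s = doc.sentence_of(ent.span)
        if s is sent and _entity_head_index(doc, sent, ent) == idx:
            return ent
    return None


def modifier_coordination(doc: Document) -> None:
    """Corrective: a conj edge attached to a noun whose pre-modifier is the
    intended entity conjunct is re-pointed to that modifier entity."""
    for sent in doc.sentences:
        new_edges = []
        for e in sent.graph:
            if (
                e.label == "conj"
                and _is_entity_head(doc, sent, e.dependent) is not None
                and _is_entity_head(doc, sent, e.governor) is None
            ):
                mods = sent.graph.dependents(e.governor, {"nn", "amod"})
                ent_mods = [
                    m for m in mods if _is_entity_head(doc, sent, m.dependent)
                ]
                if ent_mods:
                    new_edges.append(
                        DependencyEdge("conj", ent_mods[-1].dependent, e.dependent)
                    )
                    continue
            new_edges.append(e)
        sent.graph.replace(new_edges)


def term_coordination(doc: Document) -> None:
    """Serial coordination over punctuation: ``A , B (, ) and C`` gains conj
    edges from the first entity conjunct to every later one, skipping
    parenthetical asides (typically abbreviations)."""
    for sent in doc.sentences:
        heads = {
            t.index
            for t in sent.tokens
            if _is_entity_head(doc, sent, t.index) is not None
        }
        runs: list[list[int]] = []
        run: list[int] = []
        expecting = "item"
        depth = 0
        for t in sent.tokens:
            if t.text in "([":
                depth += 1
                continue
            if t.text in ")]":
                depth = max(0, depth - 1)
                continue
            if depth:
                continue
            if t.index in heads and expecting == "item":
                run.append(t.index)
                expecting = "sep"
            elif t.text == "," and expecting == "sep":
                expecting = "item"
            elif t.pos == "CC" and expecting in ("sep", "item"):
                expecting = "item"
            else:
                if len(run) >= 3:
                    runs.append(run)
                run, expecting = [], "item"
                if t.index in heads:
                    run.append(t.index)
                    expecting = "sep"
        if len(run) >= 3:
            runs.append(run)
        for r in runs:
            existing = {
                (e.governor, e.dependent) for e in sent.graph if e.label == "conj"
            }
            for other in r[1:]:
                if (r[0], other) not in existing:
                    sent.graph.add("conj", r[0], other)


def coordination(doc: Document) -> None:
    """Re-head conjunct edges onto the coordinating-conjunction node.

    After this transformation the cc token governs every conjunct through
    ``conj_arg`` edges and inherits the incoming edges of the first
    conjunct, so paths to a coordination pass through its node.
    """
    for sent in doc.sentences:
        changed = True
        while changed:
            changed = False
            for e in list(sent.graph):
                if e.label != "conj":
                    continue
                g = e.governor
                conjs = [x.dependent for x in sent.graph.dependents(g, {"conj"})]
                ccs = [x.dependent for x in sent.graph.dependents(g, {"cc"})]
                cc = ccs[-1] if ccs else None
                if cc is None:
                    # no overt conjunction token attached; leave conj edges
                    continue
                new_edges = []
                members = [g] + conjs
                for edge in sent.graph:
                    if edge.label == "conj" and edge.governor == g:
                        continue
                    if edge.label == "cc" and edge.governor == g:
                        continue
                    if edge.dependent == g and edge.governor not in members:
                        new_edges.append(
                            DependencyEdge(edge.label, edge.governor, cc)
                        )
                        continue
                    new_edges.append(edge)
                for m in members:
                    new_edges.append(DependencyEdge("conj_arg", cc, m))
                sent.graph.replace(new_edges)
                changed = True
                break


def np_internal(doc: Document) -> None:
    """Dependency-based NP chunking.

    A chunk is a nominal head together with its contiguous left-side
    modifier dependents (determiners, adjectives, noun compounds,
    possessives, numbers); of-PPs are excluded, so the chunk head is the
    phrase's rightmost non-punctuation token.
    """
    for sent in doc.sentences:
        modifier_of = {}
        for e in sent.graph:
            if e.label in MODIFIER_LABELS:
                modifier_of.setdefault(e.governor, []).append(e.dependent)
        # tokens absorbed into a merged entity node belong to that node
        entity_node = {}
        for ent in doc.entities:
            if doc.sentence_of(ent.span) is sent:
                head = _entity_head_index(doc, sent, ent)
                for i in _entity_token_indices(doc, sent, ent):
                    entity_node[i] = head
        chunks = []
        for t in sent.tokens:
            if t.pos not in NOMINAL_POS:
                continue
            if any(
                e.label in MODIFIER_LABELS
                for e in sent.graph.governors(t.index)
            ):
                continue  # this token premodifies another head
            left = t.index
            mods = set()
            frontier = [t.index]
            while frontier:
                node = frontier.pop()
                for d in modifier_of.get(node, []):
                    if d not in mods:
                        mods.add(d)
                        frontier.append(d)
            for i in range(t.index - 1, -1, -1):
                if i in mods or entity_node.get(i) in mods or entity_node.get(i) == t.index:
                    left = i
                else:
                    break
            chunks.append(
                (Span(sent.tokens[left].span.start, t.span.end), t.index)
            )
        sent.chunks = chunks


TRANSFORMATIONS = {
    "SemanticEnrichment": semantic_enrichment,
    "PPAttachmentCorrection": pp_attachment_correction,
    "ModifierCoordination": modifier_coordination,
    "TermCoordination": term_coordination,
    "Coordination": coordination,
    "NPInternal": np_internal,
}

DEFAULT_TRANSFORMATIONS = list(TRANSFORMATIONS)


def apply_transformations(doc: Document, names: Optional[list[str]] = None) -> Document:
    """Apply the named transformations to the document, in the given order."""
    for name in DEFAULT_TRANSFORMATIONS if names is None else names:
        fn = TRANSFORMATIONS.get(name)
        if fn is None:
            raise ConfigError(f"unknown transformation {name!r}")
        fn(doc)
    return doc


# --------------------------------------------------------------------- #
# coordination recognition


def recognize_coordinations(doc: Document) -> list[Conjunction]:
    """Group syntactically coordinated, semantically compatible entities.

    One :class:`Conjunction` per maximal coordinated set of entities that
    share a semantic type or group.
    """
    out: list[Conjunction] = []
    for sent in doc.sentences:
        head_to_entity = {}
        for ent in doc.entities:
            if doc.sentence_of(ent.span) is sent:
                head_to_entity[_entity_head_index(doc, sent, ent)] = ent
        # connected components over conj / conj_arg edges
        import networkx as nx

        g = nx.Graph()
        for e in sent.graph:
            if e.label in ("conj", "conj_arg"):
                g.add_edge(e.governor, e.dependent)
        for comp in nx.connected_components(g) if g.number_of_nodes() else []:
            ents = [head_to_entity[i] for i in comp if i in head_to_entity]
            if len(ents) < 2:
                continue
            by_group: dict[str, list[Entity]] = {}
            for ent in ents:
                by_group.setdefault(ent.semgroup, []).append(ent)
            for group, members in by_group.items():
                if len(members) < 2:
                    continue
                members.sort(key=lambda x: x.span.start)
                conj = Conjunction(
                    conjuncts=members,
                    span=Span(members[0].span.start, members[-1].span.end),
                    semgroup=group,
                )
                if conj not in out:
                    out.append(conj)
    doc.conjunctions = out
    return out


# --------------------------------------------------------------------- #
# sections


def _lines_with_offsets(text: str):
    start = 0
    for line in text.split("\n"):
        yield line, start, start + len(line)
        start += len(line) + 1


def segment_sections(doc: Document, mode: str = "none") -> list[Section]:
    """Partition the document's sentences into header-delimited sections.

    ``spl`` matches a configured header list at line starts; ``discharge``
    marks a line as a header iff its last token is a colon and the line
    contains at least one capitalized word; ``none`` yields one section.
    """
    if mode == "none":
        sections = [
            Section(header=None, span=Span(0, max(1, len(doc.text))), sentences=list(doc.sentences))
        ]
        doc.sections = sections
        return sections

    header_positions: list[tuple[int, str]] = []  # (line start offset, header)
    if mode == "spl":
        headers = load_spl_headers()
        pattern = re.compile(
            r"^\s*(" + "|".join(re.escape(h) for h in headers) + r")\b",
            re.IGNORECASE,
        )
        for line, s, _e in _lines_with_offsets(doc.text):
            m = pattern.match(line)
            if m:
                header_positions.append((s, m.group(1)))
    elif mode == "discharge":
        for line, s, _e in _lines_with_offsets(doc.text):
            stripped = line.rstrip()
            if not stripped:
                continue
            if stripped.endswith(":") and any(
                w[:1].isupper() for w in stripped.split()
            ):
                header_positions.append((s, stripped.rstrip(":").strip()))
    else:
        raise ConfigError(f"unknown section mode {mode!r}")

    if not header_positions:
        return segment_sections(doc, "none")

    sections: list[Section] = []
    bounds = [p for p, _ in header_positions] + [len(doc.text)]
    if header_positions[0][0] > 0:
        pre = [s for s in doc.sentences if s.span.start < header_positions[0][0]]
        if pre:
            sections.append(
                Section(None, Span(0, header_positions[0][0]), pre)
            )
    for i, (pos, header) in enumerate(header_positions):
        end = bounds[i + 1]
        sents = [s for s in doc.sentences if pos <= s.span.start < end]
        if end > pos:
            sections.append(Section(header, Span(pos, end), sents))
    doc.sections = sections
    return sections


# --------------------------------------------------------------------- #
# discourse-level list recognition

_BULLET = re.compile(r"^\s*(?:[-*•]|\d+[.)])?\s*")


def detect_discourse_lists(
    doc: Document, sections: Optional[list[Section]] = None
) -> list[Conjunction]:
    """Treat line-initial entities of one semantic group within a section as
    a discourse-level conjunct set; entities coordinated with a member on
    the same line join the set."""
    sections = sections if sections is not None else (doc.sections or segment_sections(doc, "none"))
    out: list[Conjunction] = []
    lines = list(_lines_with_offsets(doc.text))
    for section in sections:
        by_group: dict[str, list[Entity]] = {}
        section_entities = [
            e for e in doc.entities if section.span.contains(e.span)
        ]
        for line, s, e in lines:
            if not (section.span.start <= s < section.span.end):
                continue
            content_start = s + _BULLET.match(line).end()
            initial = [
                ent for ent in section_entities if ent.span.start == content_start
            ]
            for ent in initial:
                members = by_group.setdefault(ent.semgroup, [])
                if ent not in members:
                    members.append(ent)
                # same-line coordinated partners join the set
                for conj in doc.conjunctions:
                    if ent in conj.conjuncts:
                        for other in conj.conjuncts:
                            if (
                                other is not ent
                                and s <= other.span.start < e
                                and other not in members
                            ):
                                members.append(other)
        for group, members in by_group.items():
            if len(members) >= 2:
                members.sort(key=lambda x: x.span.start)
                out.append(
                    Conjunction(
                        conjuncts=members,
                        span=Span(members[0].span.start, members[-1].span.end),
                        semgroup=group,
                        discourse=True,
                    )
                )
    doc.discourse_sets = out
    return out


def preprocess(
    doc: Document,
    transformations: Optional[list[str]] = None,
    section_mode: str = "none",
    discourse_lists: bool = False,
) -> Document:
    """Run the full pre-resolution pipeline in order."""
    apply_transformations(doc, transformations)
    recognize_coordinations(doc)
    segment_sections(doc, section_mode)
    if discourse_lists:
        detect_discourse_lists(doc)
    return doc
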