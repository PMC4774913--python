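"""Core document model for coreference resolution.

A :class:`Document` bundles raw text, sentence/token structure with
dependency graphs, named entities with semantic types, coordinated-entity
conjunctions, detected coreferential mentions, and section structure.
Character offsets are 0-based half-open throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx


class Span(tuple):
    """A character interval ``[start, end)`` over the document text."""

    def __new__(cls, start: int, end: int):
        if end <= start:
            raise ValueError(f"empty or inverted span ({start}, {end})")
        return super().__new__(cls, (start, end))

    @property
    def start(self) -> int:
        return self[0]

    @property
    def end(self) -> int:
        return self[1]

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Token:
    """A single token with lemma, Penn POS tag and character span."""

    index: int  # 0-based position within the owning sentence
    text: str
    lemma: str
    pos: str
    span: Span

    def is_punct(self) -> bool:
        return not any(ch.isalnum() for ch in self.text)


# Dependency labels that rules treat as subject / object / prepositional /
# coordination constructions (Stanford-style; UD input is mapped on read).
SUBJECT_LABELS = {"nsubj", "nsubjpass"}
OBJECT_LABELS = {"dobj", "iobj"}
PREP_LABELS = {"prep", "pobj"}
COORD_LABELS = {"cc", "conj", "conj_arg", "preconj"}
APPOSITIVE_LABELS = {"appos", "abbrev"}
CLAUSAL_COMPLEMENT_LABELS = {"infmod", "ccomp", "xcomp", "vmod"}


@dataclass(frozen=True)
class DependencyEdge:
    label: str
    governor: int  # token index within sentence
    dependent: int


class DependencyGraph:
    """Labelled dependency edges over one sentence's tokens.

    Nodes are token indices.  After the semantic-enrichment transformation,
    multi-token entities are collapsed onto their head token, so a node may
    stand for a merged entity.  Undirected path queries are backed by a
    networkx graph rebuilt lazily on mutation.
    """

    def __init__(self, edges: Iterable[DependencyEdge] = ()):
        self.edges: list[DependencyEdge] = list(edges)
        self._nx: Optional[nx.Graph] = None

    def add(self, label: str, governor: int, dependent: int) -> None:
        self.edges.append(DependencyEdge(label, governor, dependent))
        self._nx = None

    def remove(self, edge: DependencyEdge) -> None:
        self.edges.remove(edge)
        self._nx = None

    def replace(self, edges: Iterable[DependencyEdge]) -> None:
        self.edges = list(edges)
        self._nx = None

    def governors(self, dependent: int, labels: Optional[set] = None):
        return [
            e
            for e in self.edges
            if e.dependent == dependent and (labels is None or e.label in labels)
        ]

    def dependents(self, governor: int, labels: Optional[set] = None):
        return [
            e
            for e in self.edges
            if e.governor == governor and (labels is None or e.label in labels)
        ]

    def _graph(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            for e in self.edges:
                g.add_edge(e.governor, e.dependent, label=e.label)
            self._nx = g
        return self._nx

    def path(self, a: int, b: int) -> Optional[list[DependencyEdge]]:
        """Undirected shortest dependency path between two token nodes.

        Returns the edges along the path, or None when disconnected.
        """
        if a == b:
            return []
        g = self._graph()
        if a not in g or b not in g:
            return None
        try:
            nodes = nx.shortest_path(g, a, b)
        except nx.NetworkXNoPath:
            return None
        out = []
        for u, v in zip(nodes, nodes[1:]):
            label = g.edges[u, v]["label"]
            # recover the directed edge for role tests
            directed = next(
                (
                    e
                    for e in self.edges
                    if {e.governor, e.dependent} == {u, v} and e.label == label
                ),
                DependencyEdge(label, u, v),
            )
            out.append(directed)
        return out

    def path_length(self, a: int, b: int) -> Optional[int]:
        p = self.path(a, b)
        return None if p is None else len(p)

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)


@dataclass
class Sentence:
    index: int  # 0-based document position
    span: Span
    tokens: list[Token]
    graph: DependencyGraph = field(default_factory=DependencyGraph)
    # NP chunks filled in by the NP-internal transformation: (span, head index)
    chunks: list[tuple[Span, int]] = field(default_factory=list)

    def token_at(self, offset: int) -> Optional[Token]:
        for t in self.tokens:
            if t.span.start <= offset < t.span.end:
                return t
        return None

    def tokens_in(self, span: Span) -> list[Token]:
        return [t for t in self.tokens if t.span.overlaps(span)]


class MentionType(enum.Enum):
    PersonalPronoun = "PersonalPronoun"
    PossessivePronoun = "PossessivePronoun"
    DemonstrativePronoun = "DemonstrativePronoun"
    RelativePronoun = "RelativePronoun"
    IndefinitePronoun = "IndefinitePronoun"
    DistributivePronoun = "DistributivePronoun"
    ReciprocalPronoun = "ReciprocalPronoun"
    DefiniteNP = "DefiniteNP"
    DemonstrativeNP = "DemonstrativeNP"
    IndefiniteNP = "IndefiniteNP"
    DistributiveNP = "DistributiveNP"
    ZeroArticleNP = "ZeroArticleNP"


PRONOUN_MENTION_TYPES = {
    MentionType.PersonalPronoun,
    MentionType.PossessivePronoun,
    MentionType.DemonstrativePronoun,
    MentionType.RelativePronoun,
    MentionType.IndefinitePronoun,
    MentionType.DistributivePronoun,
    MentionType.ReciprocalPronoun,
}

# brat text-bound annotation names for mention subcategories <-> MentionType
MENTION_BRAT_NAMES = {
    MentionType.PersonalPronoun: "personal_pronoun",
    MentionType.PossessivePronoun: "possessive_pronoun",
    MentionType.DemonstrativePronoun: "demonstrative_pronoun",
    MentionType.RelativePronoun: "relative_pronoun",
    MentionType.IndefinitePronoun: "indefinite_pronoun",
    MentionType.DistributivePronoun: "distributive_pronoun",
    MentionType.ReciprocalPronoun: "reciprocal_pronoun",
    MentionType.DefiniteNP: "definite_np",
    MentionType.DemonstrativeNP: "demonstrative_np",
    MentionType.IndefiniteNP: "indefinite_np",
    MentionType.DistributiveNP: "distributive_np",
    MentionType.ZeroArticleNP: "zero_article_np",
}
BRAT_NAME_TO_MENTION = {v: k for k, v in MENTION_BRAT_NAMES.items()}


# Default fine semantic type -> coarse semantic group map.  Users may supply
# their own; drug, drug_class and substance collapse into one group because
# drug/substance coreference is what drug-label strategies whitelist.
DEFAULT_TYPE_SYSTEM = {
    "drug": "drug_substance",
    "drug_class": "drug_substance",
    "substance": "drug_substance",
    "Protein": "protein",
    "protein": "protein",
    "gene": "protein",
    "Problem": "problem",
    "problem": "problem",
    "Test": "test",
    "test": "test",
    "Treatment": "treatment",
    "treatment": "treatment",
    "Person": "person",
    "person": "person",
    "population": "person",
}

# Semantic groups whose members are animate for phi-feature purposes.
ANIMATE_GROUPS = {"person"}


@dataclass
class Entity:
    """A named entity with fine semantic type and coarse semantic group."""

    span: Span
    semtype: str
    semgroup: Optional[str] = None
    concept: Optional[str] = None
    fragments: Optional[list[Span]] = None  # discontinuous brat spans

    def __post_init__(self):
        if self.semgroup is None:
            self.semgroup = DEFAULT_TYPE_SYSTEM.get(self.semtype, self.semtype)

    def __hash__(self):
        return hash((self.span, self.semtype))

    def __eq__(self, other):
        return (
            isinstance(other, Entity)
            and self.span == other.span
            and self.semtype == other.semtype
        )


@dataclass
class Conjunction:
    """A coordinated set of semantically compatible entities.

    ``discourse=True`` marks conjunct sets assembled from itemized lists
    rather than from within-sentence syntactic coordination.
    """

    conjuncts: list[Entity]
    span: Span
    semgroup: str
    discourse: bool = False

    def __post_init__(self):
        if len(self.conjuncts) < 2:
            raise ValueError("a conjunction needs at least two conjuncts")

    def __hash__(self):
        return hash((self.span, tuple(c.span for c in self.conjuncts)))

    def __eq__(self, other):
        return (
            isinstance(other, Conjunction)
            and self.span == other.span
            and [c.span for c in self.conjuncts] == [c.span for c in other.conjuncts]
        )


@dataclass
class Mention:
    """A typed coreferential expression."""

    span: Span
    mtype: MentionType
    head: Optional[tuple[int, int]] = None  # (sentence index, token index)
    semtype: Optional[str] = None
    semgroup: Optional[str] = None
    reflexive: bool = False
    pleonastic: bool = False
    rigid_designator: bool = False
    in_appositive: bool = False

    def __hash__(self):
        return hash((self.span, self.mtype))

    def __eq__(self, other):
        return (
            isinstance(other, Mention)
            and self.span == other.span
            and self.mtype == other.mtype
        )


SemanticItem = Union[Entity, Conjunction, Mention]


class CoreferenceType(enum.Enum):
    anaphora = "anaphora"
    cataphora = "cataphora"
    appositive = "appositive"
    predicate_nominative = "predicate_nominative"


# Role labels per coreference type, in (mention role, referent role) order.
ROLE_LABELS = {
    CoreferenceType.anaphora: ("Anaphor", "Antecedent"),
    CoreferenceType.cataphora: ("Cataphor", "Consequent"),
    CoreferenceType.appositive: ("Attribute", "Head"),
    CoreferenceType.predicate_nominative: ("Attribute", "Head"),
}


@dataclass
class CoreferenceLink:
    """A typed pairwise coreference relation with named roles."""

    ctype: CoreferenceType
    mention: SemanticItem
    referent: SemanticItem

    @property
    def roles(self) -> list[tuple[str, SemanticItem]]:
        m_role, r_role = ROLE_LABELS[self.ctype]
        return [(m_role, self.mention), (r_role, self.referent)]

    def key(self):
        return (self.ctype.value, _item_span(self.mention), _item_span(self.referent))

    def __hash__(self):
        return hash(self.key())

    def __eq__(self, other):
        return isinstance(other, CoreferenceLink) and self.key() == other.key()


def _item_span(item: SemanticItem) -> Span:
    return item.span


@dataclass
class Chain:
    """A cluster of mentions/entities referring to one discourse entity."""

    members: list[SemanticItem]
    identity: Optional[str] = None

    def spans(self) -> set[Span]:
        return {m.span for m in self.members}


@dataclass
class Section:
    header: Optional[str]
    span: Span
    sentences: list[Sentence]


@dataclass
class Document:
    """The unit of resolution: text plus all linguistic and semantic layers."""

    text: str
    sentences: list[Sentence]
    entities: list[Entity] = field(default_factory=list)
    conjunctions: list[Conjunction] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    sections: list[Section] = field(default_factory=list)
    discourse_sets: list[Conjunction] = field(default_factory=list)
    doc_id: str = "doc"

    # ------------------------------------------------------------------ #

    def slice(self, span: Span) -> str:
        return self.text[span.start : span.end]

    def sentence_of(self, span: Span) -> Optional[Sentence]:
        for s in self.sentences:
            if s.span.start <= span.start < s.span.end:
                return s
        return None

    def sentence_index_of(self, span: Span) -> int:
        s = self.sentence_of(span)
        return -1 if s is None else s.index

    def align_span(self, span: Span) -> tuple[list[Token], bool]:
        """Minimal token cover of a span.

        Returns ``(tokens, partial)`` where ``partial`` flags spans that
        start or end mid-token.  Raises ValueError when the span crosses
        no token at all.
        """
        if span.start < 0 or span.end > len(self.text):
            raise ValueError(f"span {span} outside document text")
        covered = []
        for sent in self.sentences:
            if not sent.span.overlaps(span):
                continue
            covered.extend(t for t in sent.tokens if t.span.overlaps(span))
        if not covered:
            raise ValueError(f"span {span} covers no token")
        partial = covered[0].span.start < span.start or covered[-1].span.end > span.end
        return covered, partial

    def head_token_of(self, item: SemanticItem) -> Optional[tuple[Sentence, Token]]:
        """Token standing for an item in dependency computations.

        Mentions use their recorded head; entities and conjunctions use the
        rightmost token of the (first fragment of the) span — for merged
        entity nodes this is the node the graph retains.
        """
        if isinstance(item, Mention) and item.head is not None:
            s_idx, t_idx = item.head
            sent = self.sentences[s_idx]
            return sent, sent.tokens[t_idx]
        span = item.span
        if isinstance(item, Entity) and item.fragments:
            span = item.fragments[0]
        if isinstance(item, Conjunction):
            span = item.conjuncts[0].span
        sent = self.sentence_of(span)
        if sent is None:
            return None
        toks = [t for t in sent.tokens if t.span.overlaps(span) and not t.is_punct()]
        if not toks:
            toks = sent.tokens_in(span)
        return (sent, toks[-1]) if toks else None

    def validate(self) -> None:
        """Check the structural invariants of the model; raise on violation."""
        for sent in self.sentences:
            prev_end = None
            for t in sent.tokens:
                if self.slice(t.span) != t.text:
                    raise ValueError(
                        f"token text {t.text!r} does not match its span {t.span}"
                    )
                if not (sent.span.start <= t.span.start and t.span.end <= sent.span.end):
                    raise ValueError("token span escapes its sentence")
                if prev_end is not None and t.span.start < prev_end:
                    raise ValueError("overlapping or unordered token spans")
                prev_end = t.span.end
            n = len(sent.tokens)
            for e in sent.graph:
                if not (0 <= e.governor < n and 0 <= e.dependent < n):
                    raise ValueError("dependency edge endpoint outside sentence")
        for item in list(self.entities) + list(self.mentions):
            if not self.slice(item.span):
                raise ValueError("empty annotation span")
        if self.sections:
            seen = set()
            for sec in self.sections:
                for s in sec.sentences:
                    if s.index in seen:
                        raise ValueError("sentence assigned to two sections")
                    seen.add(s.index)
            if seen != {s.index for s in self.sentences}:
                raise ValueError("sections do not partition the sentences")


def item_text(doc: Document, item: SemanticItem) -> str:
    return doc.slice(item.span)
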