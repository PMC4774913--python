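"""Post-scoring referent filtering: threshold, top score, salience.

Salience measures: ``Default`` is textual proximity (number of intervening
tokens, counted flatly across sentence boundaries); ``Parse`` is the
undirected dependency-path distance, with 2 added per sentence of
separation for cross-sentence pairs, falling back to Default on ties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .agreement import ScoredCandidate
from .types import Document, Mention


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PostScoringSpec:
    name: str  # Threshold | TopScore | Salience
    parameter: Optional[Union[int, str]] = None

    def __post_init__(self):
        if self.name == "Threshold" and not isinstance(self.parameter, int):
            raise ConfigError("Threshold requires an integer parameter")
        if self.name == "Salience" and self.parameter not in ("Default", "Parse"):
            raise ConfigError("Salience requires measure Default or Parse")


_SPEC_RE = re.compile(r"^\s*([A-Za-z]+)\s*(?:\(\s*([A-Za-z0-9]+)\s*\))?\s*$")


def parse_postscoring_spec(text: str) -> PostScoringSpec:
    m = _SPEC_RE.match(text)
    if not m:
        raise ConfigError(f"cannot parse post-scoring spec {text!r}")
    name, param = m.groups()
    if name not in ("Threshold", "TopScore", "Salience"):
        raise ConfigError(f"unknown post-scoring filter {name!r}")
    if param is not None and param.isdigit():
        param = int(param)
    return PostScoringSpec(name, param)


def _intervening_tokens(doc: Document, a_span, b_span) -> int:
    lo, hi = sorted([a_span, b_span], key=lambda s: (s.start, s.end))
    count = 0
    for sent in doc.sentences:
        for t in sent.tokens:
            if lo.end <= t.span.start and t.span.end <= hi.start:
                count += 1
    return count


def _depth_to_root(sent, token_index: int) -> int:
    dependents = {e.dependent for e in sent.graph}
    roots = [
        t.index
        for t in sent.tokens
        if t.index not in dependents and sent.graph.dependents(t.index)
    ]
    best = None
    for r in roots:
        d = sent.graph.path_length(token_index, r)
        if d is not None and (best is None or d < best):
            best = d
    return best if best is not None else len(sent.tokens)


def salience_distance(
    mention: Mention, cand, measure: str, doc: Document
) -> float:
    """Distance from mention to candidate under the given salience measure
    (smaller is more salient)."""
    if measure == "Default":
        return _intervening_tokens(doc, mention.span, cand.span)
    if measure != "Parse":
        raise ConfigError(f"unknown salience measure {measure!r}")
    m = doc.head_token_of(mention)
    c = doc.head_token_of(cand)
    if m is None or c is None:
        return _intervening_tokens(doc, mention.span, cand.span)
    m_sent, m_tok = m
    c_sent, c_tok = c
    if m_sent is c_sent:
        d = m_sent.graph.path_length(m_tok.index, c_tok.index)
        return d if d is not None else len(m_sent.tokens)
    sent_distance = abs(m_sent.index - c_sent.index)
    return (
        _depth_to_root(m_sent, m_tok.index)
        + _depth_to_root(c_sent, c_tok.index)
        + 2 * sent_distance
    )


def apply_postscoring(
    scored: Sequence[ScoredCandidate],
    specs: Sequence[PostScoringSpec],
    mention: Mention,
    doc: Document,
):
    """Apply post-scoring filters sequentially; return the selected referent
    or None when no candidate survives.

    Remaining ties are broken deterministically: smallest span-start
    distance to the mention, then leftmost candidate.
    """
    pool = list(scored)
    for spec in specs:
        if not pool:
            return None
        if spec.name == "Threshold":
            pool = [s for s in pool if s.score >= spec.parameter]
        elif spec.name == "TopScore":
            best = max(s.score for s in pool)
            pool = [s for s in pool if s.score == best]
        elif spec.name == "Salience":
            if spec.parameter == "Parse":
                key = lambda s: (
                    salience_distance(mention, s.candidate, "Parse", doc),
                    salience_distance(mention, s.candidate, "Default", doc),
                )
            else:
                key = lambda s: salience_distance(
                    mention, s.candidate, "Default", doc
                )
            best = min(key(s) for s in pool)
            pool = [s for s in pool if key(s) == best]
        else:
            raise ConfigError(f"unknown post-scoring filter {spec.name!r}")
    if not pool:
        return None
    pool.sort(
        key=lambda s: (
            abs(s.candidate.span.start - mention.span.start),
            s.candidate.span.start,
        )
    )
    return pool[0].candidate
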