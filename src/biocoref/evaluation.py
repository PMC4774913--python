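"""Coreference evaluation: pairwise link P/R/F1 with exact or approximate
span matching, and chain metrics (MUC, B-CUBED, CEAF, BLANC) with their
unweighted F1 average."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import Chain, CoreferenceLink, Span


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    @classmethod
    def make(cls, p, r):
        return cls(p, r, _f1(p, r))


@dataclass
class MetricReport:
    muc: PRF
    bcubed: PRF
    ceaf: PRF
    blanc: Optional[PRF] = None

    @property
    def average_f1(self) -> float:
        """Unweighted F1 average over B-CUBED, MUC and CEAF."""
        return (self.muc.f1 + self.bcubed.f1 + self.ceaf.f1) / 3


# --------------------------------------------------------------------- #
# pairwise evaluation


def _span_match(a: Span, b: Span, mode: str) -> bool:
    if mode == "exact":
        return a == b
    if mode == "approximate":
        return a.overlaps(b)
    raise ValueError(f"unknown match mode {mode!r}")


def _link_match(g: CoreferenceLink, p: CoreferenceLink, mode: str) -> bool:
    if g.ctype != p.ctype:
        return False
    return _span_match(g.mention.span, p.mention.span, mode) and _span_match(
        g.referent.span, p.referent.span, mode
    )


def pairwise_prf(
    gold: Sequence[CoreferenceLink],
    pred: Sequence[CoreferenceLink],
    mode: str = "approximate",
) -> PRF:
    """Precision/recall/F1 over typed mention-referent pairs.

    A predicted link is correct when a gold link of the same coreference
    type matches both of its elements under the chosen span-matching mode;
    each gold link can be matched at most once (maximum bipartite
    matching).  Empty gold and empty prediction score 1 by convention.
    """
    if not gold and not pred:
        return PRF(1.0, 1.0, 1.0)
    g = nx.Graph()
    g_nodes = [("g", i) for i in range(len(gold))]
    p_nodes = [("p", j) for j in range(len(pred))]
    g.add_nodes_from(g_nodes, bipartite=0)
    g.add_nodes_from(p_nodes, bipartite=1)
    for i, gl in enumerate(gold):
        for j, pl in enumerate(pred):
            if _link_match(gl, pl, mode):
                g.add_edge(("g", i), ("p", j))
    matching = nx.bipartite.maximum_matching(g, top_nodes=g_nodes)
    matched = sum(1 for k in matching if k[0] == "g")
    p = matched / len(pred) if pred else 0.0
    r = matched / len(gold) if gold else 0.0
    return PRF.make(p, r)


# --------------------------------------------------------------------- #
# chain metrics


def _normalize(chains) -> list[frozenset]:
    out = []
    seen = set()
    for c in chains:
        members = c.members if isinstance(c, Chain) else c
        keys = frozenset(
            m.span if hasattr(m, "span") else m for m in members
        )
        if not keys:
            continue
        if seen & keys:
            raise ValueError("chains are not a partition: shared mention")
        seen |= keys
        out.append(keys)
    return out


def _with_singletons(chains: list[frozenset], universe: set) -> list[frozenset]:
    covered = set().union(*chains) if chains else set()
    return chains + [frozenset([m]) for m in universe - covered]


def muc_prf(gold: list[frozenset], pred: list[frozenset]) -> PRF:
    """Link-based MUC score (Vilain et al.)."""

    def score(keys: list[frozenset], response: list[frozenset]):
        num = den = 0
        for k in keys:
            parts = {i for m in k for i, r in enumerate(response) if m in r}
            missing = sum(1 for m in k if not any(m in r for r in response))
            partitions = len(parts) + missing
            num += len(k) - partitions
            den += len(k) - 1
        return num / den if den else 0.0

    r = score(gold, pred)
    p = score(pred, gold)
    return PRF.make(p, r)


def bcubed_prf(gold: list[frozenset], pred: list[frozenset]) -> PRF:
    universe = set().union(*gold, *pred) if (gold or pred) else set()
    g = _with_singletons(gold, universe)
    p = _with_singletons(pred, universe)

    def chain_of(chains, m):
        return next(c for c in chains if m in c)

    if not universe:
        return PRF(1.0, 1.0, 1.0)
    prec = sum(
        len(chain_of(p, m) & chain_of(g, m)) / len(chain_of(p, m)) for m in universe
    ) / len(universe)
    rec = sum(
        len(chain_of(p, m) & chain_of(g, m)) / len(chain_of(g, m)) for m in universe
    ) / len(universe)
    return PRF.make(prec, rec)


def ceaf_prf(
    gold: list[frozenset], pred: list[frozenset], variant: str = "mention"
) -> PRF:
    """CEAF with optimal one-to-one chain alignment (assignment solver).

    ``mention`` uses the mention-overlap similarity (phi-3, the default);
    ``entity`` the normalized similarity 2|g∩p|/(|g|+|p|) (phi-4).
    """
    universe = set().union(*gold, *pred) if (gold or pred) else set()
    g = _with_singletons(gold, universe)
    p = _with_singletons(pred, universe)
    if not g or not p:
        return PRF(1.0, 1.0, 1.0)

    def phi(a: frozenset, b: frozenset) -> float:
        if variant == "mention":
            return len(a & b)
        return 2 * len(a & b) / (len(a) + len(b))

    sim = np.zeros((len(g), len(p)))
    for i, a in enumerate(g):
        for j, b in enumerate(p):
            sim[i, j] = phi(a, b)
    rows, cols = linear_sum_assignment(-sim)
    best = sim[rows, cols].sum()
    if variant == "mention":
        denom_r = sum(len(a) for a in g)
        denom_p = sum(len(b) for b in p)
    else:
        denom_r = len(g)
        denom_p = len(p)
    return PRF.make(best / denom_p if denom_p else 0.0, best / denom_r if denom_r else 0.0)


def blanc_prf(gold: list[frozenset], pred: list[frozenset]) -> PRF:
    """BLANC (original definition): Rand-style average over the coreference
    and non-coreference link classes."""
    universe = set().union(*gold, *pred) if (gold or pred) else set()
    if len(universe) < 2:
        return PRF(1.0, 1.0, 1.0)

    def link_sets(chains):
        coref = set()
        for c in chains:
            for a, b in combinations(sorted(c, key=repr), 2):
                coref.add(frozenset((a, b)))
        return coref

    all_pairs = {frozenset(p) for p in combinations(sorted(universe, key=repr), 2)}
    cg, cp = link_sets(gold), link_sets(pred)
    ng, np_ = all_pairs - cg, all_pairs - cp

    def prf(sg, sp):
        inter = len(sg & sp)
        p = inter / len(sp) if sp else (1.0 if not sg else 0.0)
        r = inter / len(sg) if sg else (1.0 if not sp else 0.0)
        return p, r, _f1(p, r)

    pc, rc, fc = prf(cg, cp)
    pn, rn, fn = prf(ng, np_)
    return PRF((pc + pn) / 2, (rc + rn) / 2, (fc + fn) / 2)


def chain_metrics(
    gold, pred, ceaf_variant: str = "mention", blanc: bool = True
) -> MetricReport:
    """Score predicted chains against gold chains.

    Inputs are sequences of :class:`Chain` objects (or iterables of
    hashable mention identifiers).  Chains within each side must be
    disjoint.  Unclustered mentions of either side are treated as
    singletons.
    """
    g = _normalize(gold)
    p = _normalize(pred)
    report = MetricReport(
        muc=muc_prf(g, p),
        bcubed=bcubed_prf(g, p),
        ceaf=ceaf_prf(g, p, ceaf_variant),
        blanc=blanc_prf(g, p) if blanc else None,
    )
    return report
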