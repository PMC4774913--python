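"""Strategy configurations and the left-to-right resolution engine.

A *strategy* bundles, for one coreference type and a set of mention types:
mention filters, candidate filters, a scoring function and post-scoring
filters.  A *configuration* is a set of strategies plus preprocessing and
post-processing options; three bundled configurations cover drug labels
(``spl``), clinical discharge summaries (``discharge``) and molecular
biology abstracts (``protein``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .agreement import AgreementSpec, parse_agreement_spec, score_candidate
from .candidates import CandidateFilterSpec, generate_candidates
from .mentions import apply_mention_filters, detect_mentions
from .preprocessing import preprocess
from .resources import config_path
from .selection import PostScoringSpec, apply_postscoring, parse_postscoring_spec
from .types import (
    Chain,
    Conjunction,
    CoreferenceLink,
    CoreferenceType,
    Document,
    Entity,
    Mention,
    MentionType,
)


class ConfigError(ValueError):
    pass


KNOWN_MENTION_FILTERS = {
    "ThirdPerson",
    "PleonasticIt",
    "Anaphoricity",
    "Cataphoricity",
    "CoreferentialPronoun",
}
KNOWN_CANDIDATE_FILTERS = {
    "PriorDiscourse",
    "SubsequentDiscourse",
    "WindowSize",
    "SyntacticConfiguration",
    "SyntacticConfig",
    "NounPhrase",
    "VerbPhrase",
    "SemanticClass",
    "Default",
    "Exemplification",
}

_FILTER_RE = re.compile(r"^\s*([A-Za-z]+)\s*(?:\(\s*([^)]*)\s*\))?\s*$")


def parse_candidate_filter(text: str) -> CandidateFilterSpec:
    m = _FILTER_RE.match(text)
    if not m:
        raise ConfigError(f"cannot parse candidate filter {text!r}")
    name, arg = m.groups()
    if name == "SyntacticConfig":
        name = "SyntacticConfiguration"
    if name not in KNOWN_CANDIDATE_FILTERS:
        raise ConfigError(f"unknown candidate filter {name!r}")
    param = None
    if arg:
        if name == "SemanticClass":
            param = tuple(a.strip() for a in arg.split(","))
        elif arg.isdigit():
            param = int(arg)
        else:
            param = arg.strip()
    if name == "WindowSize" and param is None:
        raise ConfigError("WindowSize requires a parameter")
    return CandidateFilterSpec(name, param)


def _filter_str(spec: CandidateFilterSpec) -> str:
    if spec.parameter is None:
        return spec.name
    if isinstance(spec.parameter, tuple):
        return f"{spec.name}({','.join(spec.parameter)})"
    return f"{spec.name}({spec.parameter})"


def _postscoring_str(spec: PostScoringSpec) -> str:
    return spec.name if spec.parameter is None else f"{spec.name}({spec.parameter})"


@dataclass
class Strategy:
    ctype: CoreferenceType
    mtypes: list[MentionType]
    mention_filters: list[str]
    candidate_filters: list[CandidateFilterSpec]
    scoring: list[AgreementSpec]
    postscoring: list[PostScoringSpec]

    def to_dict(self) -> dict:
        return {
            "ctype": self.ctype.value,
            "mtypes": [m.value for m in self.mtypes],
            "mention_filters": list(self.mention_filters),
            "candidate_filters": [_filter_str(f) for f in self.candidate_filters],
            "scoring": [str(s) for s in self.scoring],
            "postscoring": [_postscoring_str(s) for s in self.postscoring],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Strategy":
        errors = []
        try:
            ctype = CoreferenceType(d["ctype"])
        except ValueError:
            raise ConfigError(f"unknown coreference type {d.get('ctype')!r}")
        mtypes = []
        for m in d.get("mtypes", []):
            try:
                mtypes.append(MentionType(m))
            except ValueError:
                errors.append(f"unknown mention type {m!r}")
        for f in d.get("mention_filters", []):
            if f not in KNOWN_MENTION_FILTERS:
                errors.append(f"unknown mention filter {f!r}")
        try:
            cand = [parse_candidate_filter(f) for f in d.get("candidate_filters", [])]
        except ConfigError as e:
            errors.append(str(e))
            cand = []
        try:
            scoring = [parse_agreement_spec(s) for s in d.get("scoring", [])]
        except ConfigError as e:
            errors.append(str(e))
            scoring = []
        try:
            post = [parse_postscoring_spec(s) for s in d.get("postscoring", [])]
        except (ConfigError, ValueError) as e:
            errors.append(str(e))
            post = []
        if errors:
            raise ConfigError("; ".join(errors))
        if not scoring:
            raise ConfigError("strategy needs a non-empty scoring function")
        return cls(ctype, mtypes, list(d.get("mention_filters", [])), cand, scoring, post)


@dataclass
class Configuration:
    strategies: list[Strategy]
    name: str = "custom"
    transformations: Optional[list[str]] = None
    section_mode: str = "none"
    discourse_lists: bool = False
    prune_anaphora_cataphora_conflict: bool = False
    semgroup_whitelist: list[str] = field(default_factory=list)
    chain_mode: str = "pairwise"
    discharge_merge: bool = False

    def __post_init__(self):
        seen = {}
        dups = []
        for s in self.strategies:
            for m in s.mtypes:
                key = (s.ctype, m)
                if key in seen:
                    dups.append(f"{s.ctype.value}/{m.value}")
                seen[key] = s
        if dups:
            raise ConfigError(
                "duplicate strategies for: " + ", ".join(sorted(set(dups)))
            )

    def strategies_for(self, mtype: MentionType) -> list[Strategy]:
        return [s for s in self.strategies if mtype in s.mtypes]

    def mention_types(self) -> set[MentionType]:
        return {m for s in self.strategies for m in s.mtypes}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "preprocessing": {
                "transformations": self.transformations,
                "section_mode": self.section_mode,
                "discourse_lists": self.discourse_lists,
            },
            "postprocessing": {
                "prune_anaphora_cataphora_conflict": self.prune_anaphora_cataphora_conflict,
                "semgroup_whitelist": list(self.semgroup_whitelist),
                "chain_mode": self.chain_mode,
                "discharge_merge": self.discharge_merge,
            },
            "strategies": [s.to_dict() for s in self.strategies],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Configuration":
        pre = d.get("preprocessing", {})
        post = d.get("postprocessing", {})
        strategies = [Strategy.from_dict(s) for s in d.get("strategies", [])]
        return cls(
            strategies=strategies,
            name=d.get("name", "custom"),
            transformations=pre.get("transformations"),
            section_mode=pre.get("section_mode", "none"),
            discourse_lists=bool(pre.get("discourse_lists", False)),
            prune_anaphora_cataphora_conflict=bool(
                post.get("prune_anaphora_cataphora_conflict", False)
            ),
            semgroup_whitelist=list(post.get("semgroup_whitelist", [])),
            chain_mode=post.get("chain_mode", "pairwise"),
            discharge_merge=bool(post.get("discharge_merge", False)),
        )


def load_configuration(source: Union[str, Path, dict]) -> Configuration:
    """Load and validate a strategy configuration.

    ``source`` may be a path to a JSON file, JSON text, a dict, or the name
    of a bundled configuration (``spl``, ``discharge``, ``protein``).
    """
    if isinstance(source, dict):
        return Configuration.from_dict(source)
    p = Path(str(source))
    if not p.exists() and re.fullmatch(r"[a-z_]+", str(source) or ""):
        p = config_path(str(source))
    if p.exists():
        data = json.loads(p.read_text(encoding="utf-8"))
    else:
        data = json.loads(str(source))
    return Configuration.from_dict(data)


# --------------------------------------------------------------------- #
# resolution


def resolve_document(
    doc: Document,
    config: Configuration,
    mentions: Optional[Sequence[Mention]] = None,
    resources: Optional[dict] = None,
    preprocessed: bool = False,
) -> list[CoreferenceLink]:
    """Run the full left-to-right resolution loop.

    For each detected (or supplied) mention, in textual order, every
    strategy registered for its mention type is applied: candidate
    filtering, scoring, post-scoring selection.  A surviving best referent
    yields one typed link per (mention, strategy).
    """
    if not preprocessed:
        preprocess(
            doc,
            transformations=config.transformations,
            section_mode=config.section_mode,
            discourse_lists=config.discourse_lists,
        )
    if mentions is None:
        doc.mentions = detect_mentions(doc, allowed=config.mention_types())
    else:
        doc.mentions = list(mentions)

    links: list[CoreferenceLink] = []
    for mention in sorted(doc.mentions, key=lambda m: (m.span.start, m.span.end)):
        for strat in config.strategies_for(mention.mtype):
            survivors = apply_mention_filters([mention], strat.mention_filters, doc)
            if not survivors:
                continue
            cands = generate_candidates(mention, doc, strat.candidate_filters)
            scored = [
                score_candidate(mention, c, strat.scoring, doc, resources)
                for c in cands
            ]
            best = apply_postscoring(scored, strat.postscoring, mention, doc)
            if best is not None:
                links.append(
                    CoreferenceLink(ctype=strat.ctype, mention=mention, referent=best)
                )
    return links


def prune_links(
    links: Sequence[CoreferenceLink], config: Configuration
) -> list[CoreferenceLink]:
    """Post-resolution pruning.

    A pronoun participating in both an anaphoric and a cataphoric link
    keeps only the cataphoric one; with a non-empty semantic-group
    whitelist, links whose referent falls outside it are removed.
    """
    out = list(links)
    if config.prune_anaphora_cataphora_conflict:
        cataphoric = {
            l.mention.span
            for l in out
            if l.ctype is CoreferenceType.cataphora
        }
        out = [
            l
            for l in out
            if not (
                l.ctype is CoreferenceType.anaphora and l.mention.span in cataphoric
            )
        ]
    if config.semgroup_whitelist:
        wl = set(config.semgroup_whitelist)

        def ref_group(item):
            return getattr(item, "semgroup", None)

        out = [l for l in out if ref_group(l.referent) in wl]
    return out


def build_chains(
    links: Sequence[CoreferenceLink],
    mode: str,
    doc: Document,
) -> Union[list[CoreferenceLink], list[Chain]]:
    """Turn mention-referent pairs into the configured output form.

    ``pairwise`` splits conjunction referents into one link per conjunct;
    ``cluster`` merges pairs transitively into chains, absorbing
    interleaved mentions whose text is a substring of a chain member of the
    same semantic type.
    """
    if mode == "pairwise":
        out = []
        for l in links:
            if isinstance(l.referent, Conjunction):
                for c in l.referent.conjuncts:
                    out.append(
                        CoreferenceLink(ctype=l.ctype, mention=l.mention, referent=c)
                    )
            else:
                out.append(l)
        return out
    if mode != "cluster":
        raise ConfigError(f"unknown chain mode {mode!r}")

    chains: list[list] = []
    index: dict = {}  # span -> chain list index

    def locate(item):
        return index.get(item.span)

    for l in links:
        pair = [l.mention]
        if isinstance(l.referent, Conjunction):
            pair.extend(l.referent.conjuncts)
        else:
            pair.append(l.referent)
        targets = sorted({locate(p) for p in pair if locate(p) is not None})
        if not targets:
            chains.append(list(pair))
            tgt = len(chains) - 1
        else:
            tgt = targets[0]  # earliest-created chain is the merge target
            for other in targets[1:]:
                chains[tgt].extend(chains[other])
                chains[other] = []
        for p in pair:
            if all(p.span != q.span for q in chains[tgt]):
                chains[tgt].append(p)
        for p in chains[tgt]:
            index[p.span] = tgt

        # interleaved mention absorption
        lo = min(p.span.start for p in pair)
        hi = max(p.span.end for p in pair)
        for m in doc.mentions:
            if m.span.start >= lo and m.span.end <= hi and locate(m) is None:
                text = doc.slice(m.span).lower()
                for p in pair:
                    same_type = getattr(m, "semtype", None) == getattr(
                        p, "semtype", None
                    )
                    if (
                        m.span != p.span
                        and same_type
                        and text
                        and text in doc.slice(p.span).lower()
                    ):
                        chains[tgt].append(m)
                        index[m.span] = tgt
                        break
    return [
        Chain(members=sorted(c, key=lambda x: x.span.start))
        for c in chains
        if len(c) >= 2
    ]


def postprocess_discharge(
    chains: Sequence[Chain],
    doc: Document,
    mentions: Optional[Sequence[Mention]] = None,
) -> list[Chain]:
    """Discharge-summary chain post-processing.

    Section-level chains and singletons are merged across sections on
    exact-string evidence; singleton *patient* mentions and second-person
    clusters are merged into the patient chain; remaining singletons are
    discarded.
    """
    import warnings

    mentions = list(mentions if mentions is not None else doc.mentions)
    pools: list[list] = [list(c.members) for c in chains]
    covered = {m.span for pool in pools for m in pool}
    for m in mentions:
        if m.span not in covered:
            pools.append([m])

    def text_of(item):
        return doc.slice(item.span).lower()

    # merge on ExactString evidence, earliest-created chain wins
    merged = True
    while merged:
        merged = False
        for i in range(len(pools)):
            if not pools[i]:
                continue
            for j in range(i + 1, len(pools)):
                if not pools[j]:
                    continue
                texts_i = {text_of(m) for m in pools[i]}
                if any(text_of(m) in texts_i for m in pools[j]):
                    seen = {m.span for m in pools[i]}
                    pools[i].extend(m for m in pools[j] if m.span not in seen)
                    pools[j] = []
                    merged = True

    # patient cluster
    patient_idx = None
    for i, pool in enumerate(pools):
        if len(pool) >= 2 and any("patient" in text_of(m).split() for m in pool):
            patient_idx = i
            break
    second_person = {"you", "your", "yourself"}
    if patient_idx is not None:
        for i, pool in enumerate(pools):
            if i == patient_idx or not pool:
                continue
            is_patient_singleton = len(pool) == 1 and text_of(pool[0]) in (
                "patient",
                "the patient",
            )
            is_second_person = any(text_of(m) in second_person for m in pool)
            if is_patient_singleton or is_second_person:
                seen = {m.span for m in pools[patient_idx]}
                pools[patient_idx].extend(
                    m for m in pool if m.span not in seen
                )
                pools[i] = []
    else:
        if any(
            len(pool) == 1 and text_of(pool[0]) in ("patient", "the patient")
            for pool in pools
        ) or any(
            any(text_of(m) in second_person for m in pool) for pool in pools
        ):
            warnings.warn("no patient chain found; second-person merge skipped")

    return [
        Chain(members=sorted(pool, key=lambda m: m.span.start))
        for pool in pools
        if len(pool) >= 2
    ]


def run_pipeline(
    doc: Document,
    config: Configuration,
    mentions: Optional[Sequence[Mention]] = None,
    resources: Optional[dict] = None,
):
    """Resolve, prune and build the configured output (links or chains)."""
    links = resolve_document(doc, config, mentions=mentions, resources=resources)
    links = prune_links(links, config)
    result = build_chains(links, config.chain_mode, doc)
    if config.chain_mode == "cluster" and config.discharge_merge:
        result = postprocess_discharge(result, doc)
    return result
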