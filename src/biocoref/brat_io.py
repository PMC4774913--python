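"""brat standoff (.txt + .ann) reader and writer.

Text-bound annotations (T lines) whose type names a mention subcategory
(``definite_np``, ``personal_pronoun``, ...) become :class:`Mention`
objects; any other type becomes an :class:`Entity` with that semantic
type.  Relation annotations (R lines) become typed
:class:`CoreferenceLink` objects with their role labels preserved.
Discontinuous spans (semicolon-separated fragments) are kept as a
fragment list; the covering span is used for alignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .types import (
    BRAT_NAME_TO_MENTION,
    MENTION_BRAT_NAMES,
    ROLE_LABELS,
    Conjunction,
    CoreferenceLink,
    CoreferenceType,
    Entity,
    Mention,
    SemanticItem,
    Span,
)


class BratError(ValueError):
    pass


def _read(source: Union[str, Path]) -> str:
    s = str(source)
    try:
        p = Path(s)
        if p.exists():
            return p.read_text(encoding="utf-8")
    except (OSError, ValueError):
        pass
    return s


def read_brat(
    text_source: Union[str, Path],
    ann_source: Union[str, Path],
    type_system: Optional[dict] = None,
) -> tuple[str, list[Entity], list[Mention], list[CoreferenceLink]]:
    """Parse a brat .txt/.ann pair.

    Returns ``(text, entities, mentions, links)``.  Spans are validated
    against the text file; mismatches raise :class:`BratError` citing the
    offending T id.
    """
    text = _read(text_source)
    ann = _read(ann_source)

    by_id: dict[str, SemanticItem] = {}
    entities: list[Entity] = []
    mentions: list[Mention] = []
    relations: list[tuple[str, str, list[tuple[str, str]]]] = []

    for raw in ann.splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("T"):
            try:
                tid, meta, surface = line.split("\t", 2)
            except ValueError as exc:
                raise BratError(f"malformed T line: {line!r}") from exc
            ttype, _, offsets = meta.partition(" ")
            fragments = []
            for frag in offsets.split(";"):
                s, e = frag.split()
                fragments.append(Span(int(s), int(e)))
            cover = Span(fragments[0].start, fragments[-1].end)
            joined = " ".join(text[f.start : f.end] for f in fragments)
            if joined != surface:
                raise BratError(
                    f"{tid}: span text {joined!r} does not match "
                    f"annotation text {surface!r}"
                )
            low = ttype.lower()
            if low in BRAT_NAME_TO_MENTION:
                m = Mention(span=cover, mtype=BRAT_NAME_TO_MENTION[low])
                mentions.append(m)
                by_id[tid] = m
            else:
                kwargs = {}
                if type_system and ttype in type_system:
                    kwargs["semgroup"] = type_system[ttype]
                ent = Entity(
                    span=cover,
                    semtype=ttype,
                    fragments=fragments if len(fragments) > 1 else None,
                    **kwargs,
                )
                entities.append(ent)
                by_id[tid] = ent
        elif line.startswith("R"):
            rid, meta = line.split("\t", 1)
            parts = meta.split()
            rtype, args = parts[0], parts[1:]
            pairs = []
            for a in args:
                role, _, ref = a.partition(":")
                pairs.append((role, ref))
            relations.append((rid, rtype, pairs))
        # other annotation kinds (events, attributes, notes) are ignored

    links: list[CoreferenceLink] = []
    for rid, rtype, pairs in relations:
        try:
            ctype = CoreferenceType(rtype)
        except ValueError as exc:
            raise BratError(f"{rid}: unknown relation type {rtype!r}") from exc
        m_role, r_role = ROLE_LABELS[ctype]
        roles = dict(pairs)
        if set(roles) != {m_role, r_role}:
            raise BratError(
                f"{rid}: expected roles {m_role}/{r_role}, got {sorted(roles)}"
            )
        for ref in roles.values():
            if ref not in by_id:
                raise BratError(f"{rid}: reference to unknown annotation {ref}")
        links.append(
            CoreferenceLink(
                ctype=ctype,
                mention=by_id[roles[m_role]],
                referent=by_id[roles[r_role]],
            )
        )
    return text, entities, mentions, links


def write_brat(
    text: str,
    entities: list[Entity],
    mentions: list[Mention],
    links: list[CoreferenceLink],
) -> str:
    """Serialize annotations as brat standoff .ann content."""
    lines = []
    ids: dict[int, str] = {}
    counter = 1
    for item in list(entities) + list(mentions):
        tid = f"T{counter}"
        counter += 1
        ids[id(item)] = tid
        if isinstance(item, Mention):
            ttype = MENTION_BRAT_NAMES[item.mtype]
            frags = [item.span]
        else:
            ttype = item.semtype
            frags = item.fragments or [item.span]
        offsets = ";".join(f"{f.start} {f.end}" for f in frags)
        surface = " ".join(text[f.start : f.end] for f in frags)
        lines.append(f"{tid}\t{ttype} {offsets}\t{surface}")

    rid = 1
    for link in links:
        referents = (
            link.referent.conjuncts
            if isinstance(link.referent, Conjunction)
            else [link.referent]
        )
        m_role, r_role = ROLE_LABELS[link.ctype]
        for ref in referents:
            lines.append(
                f"R{rid}\t{link.ctype.value} {m_role}:{_find_tid(ids, entities, mentions, link.mention)} "
                f"{r_role}:{_find_tid(ids, entities, mentions, ref)}"
            )
            rid += 1
    return "\n".join(lines) + ("\n" if lines else "")


def _find_tid(ids, entities, mentions, item) -> str:
    if id(item) in ids:
        return ids[id(item)]
    # match by span/type against the written annotations
    for cand in list(entities) + list(mentions):
        if cand == item or (
            cand.span == item.span and type(cand) is type(item)
        ):
            return ids[id(cand)]
    raise BratError(f"link references an annotation not written: {item}")
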