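"""Loaders for the plain-text lexical resources bundled with the package.

All resources are editable: pass an explicit path (or mapping) to the
functions that consume them to override the bundled defaults.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources as _ir
from pathlib import Path
from typing import Optional, Union


def _resource_text(name: str) -> str:
    return (_ir.files(__package__) / name).read_text(encoding="utf-8")


def _lines(name: str) -> list[str]:
    out = []
    for raw in _resource_text(name).splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@lru_cache(maxsize=None)
def load_label_map() -> dict:
    """UD -> Stanford-style dependency label map."""
    m = {}
    for line in _lines("ud_label_map.txt"):
        ud, st = line.split()
        m[ud] = st
    return m


@lru_cache(maxsize=None)
def load_hypernyms() -> dict[str, frozenset]:
    """Per-semantic-group hypernym headword lists."""
    groups = {}
    base = _ir.files(__package__)
    for entry in base.iterdir():
        name = entry.name
        if name.startswith("hypernyms_") and name.endswith(".txt"):
            group = name[len("hypernyms_") : -4]
            groups[group] = frozenset(w.lower() for w in _lines(name))
    return groups


@lru_cache(maxsize=None)
def load_coercion_triggers() -> dict[str, frozenset]:
    """Per-group headwords that semantically coerce possessive pronouns."""
    groups = {}
    base = _ir.files(__package__)
    for entry in base.iterdir():
        name = entry.name
        if name.startswith("coercion_") and name.endswith(".txt"):
            group = name[len("coercion_") : -4]
            groups[group] = frozenset(w.lower() for w in _lines(name))
    return groups


@lru_cache(maxsize=None)
def load_connectives() -> tuple[str, ...]:
    return tuple(w.lower() for w in _lines("connectives.txt"))


@lru_cache(maxsize=None)
def load_gender_words() -> dict[str, str]:
    out = {}
    for line in _lines("gender_words.txt"):
        word, gender = line.split()
        out[word.lower()] = gender
    return out


@lru_cache(maxsize=None)
def load_collective_nouns() -> frozenset:
    return frozenset(w.lower() for w in _lines("collective_nouns.txt"))


@lru_cache(maxsize=None)
def load_spl_headers() -> tuple[str, ...]:
    return tuple(_lines("spl_section_headers.txt"))


@lru_cache(maxsize=None)
def load_pp_affinities() -> frozenset:
    pairs = set()
    for line in _lines("pp_affinity.txt"):
        noun, prep = line.split()
        pairs.add((noun.lower(), prep.lower()))
    return frozenset(pairs)


@lru_cache(maxsize=None)
def load_exemplification_triggers() -> tuple[str, ...]:
    return tuple(w.lower() for w in _lines("exemplification_triggers.txt"))


class DictTaxonomy:
    """Minimal concept taxonomy: ``is_ancestor(a, b)`` over a parent->children map."""

    def __init__(self, parent_children: dict[str, list[str]]):
        self.children = {
            k: set(v) for k, v in parent_children.items() if not k.startswith("_")
        }

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        if ancestor == descendant:
            return False
        frontier = set(self.children.get(ancestor, ()))
        seen = set()
        while frontier:
            node = frontier.pop()
            if node == descendant:
                return True
            if node in seen:
                continue
            seen.add(node)
            frontier |= self.children.get(node, set())
        return False


@lru_cache(maxsize=None)
def load_toy_taxonomy() -> DictTaxonomy:
    return DictTaxonomy(json.loads(_resource_text("toy_taxonomy.json")))


def config_path(name: str) -> Path:
    """Path to a bundled strategy configuration (``spl``, ``discharge``, ``protein``)."""
    pkg = __package__.rsplit(".", 1)[0]
    return Path(str(_ir.files(pkg) / "configs" / f"{name}.json"))
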