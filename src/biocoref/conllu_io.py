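"""Minimal CoNLL-U reader/writer for the 10-column dialect used here.

Character offsets are reconstructed from the ``# text = ...`` sentence
comment when present, otherwise assigned deterministically by joining
tokens with single spaces.  Universal Dependencies relation labels are
mapped onto the Stanford-style labels the resolution rules are written
against (see ``resources/ud_label_map.txt``).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Union

from .resources import load_label_map
from .types import DependencyGraph, Document, Sentence, Span, Token


class ConlluError(ValueError):
    pass


def _map_label(label: str, label_map: dict) -> str:
    return label_map.get(label, label_map.get(label.split(":")[0], label))


def read_conllu(source: Union[str, Path, io.TextIOBase], doc_id: str = "doc") -> Document:
    """Parse a CoNLL-U file (or string content) into a :class:`Document`."""
    if isinstance(source, io.TextIOBase):
        content = source.read()
    else:
        content = str(source)
        try:
            p = Path(content)
            exists = p.exists()
        except (OSError, ValueError):
            exists = False
        if exists:
            content = p.read_text(encoding="utf-8")
        elif "\t" not in content and "\n" not in content:
            raise ConlluError(f"no such file: {source}")
    label_map = load_label_map()

    sentences = []
    doc_text_parts: list[str] = []
    offset = 0
    cur_rows: list[tuple] = []
    cur_text: str = ""
    lineno = 0

    def flush():
        nonlocal offset, cur_rows, cur_text
        if not cur_rows:
            return
        sent_text = cur_text
        tokens: list[Token] = []
        edges = []
        if sent_text:
            cursor = 0
            spans = []
            for form, *_ in cur_rows:
                found = sent_text.find(form, cursor)
                if found < 0:
                    raise ConlluError(
                        f"token {form!r} not found in '# text' of sentence "
                        f"{len(sentences)}"
                    )
                spans.append((found, found + len(form)))
                cursor = found + len(form)
        else:
            spans = []
            cursor = 0
            for form, *_ in cur_rows:
                spans.append((cursor, cursor + len(form)))
                cursor += len(form) + 1
            sent_text = " ".join(form for form, *_ in cur_rows)
        base = offset
        for i, (form, lemma, pos, head, deprel) in enumerate(cur_rows):
            s, e = spans[i]
            tokens.append(Token(i, form, lemma, pos, Span(base + s, base + e)))
            if head > 0:
                edges.append((_map_label(deprel, label_map), head - 1, i))
        g = DependencyGraph()
        for lab, gov, dep in edges:
            g.add(lab, gov, dep)
        sent = Sentence(
            index=len(sentences),
            span=Span(base, base + len(sent_text)),
            tokens=tokens,
            graph=g,
        )
        sentences.append(sent)
        doc_text_parts.append(sent_text)
        offset = base + len(sent_text) + 1  # newline-separated sentences
        cur_rows, cur_text = [], ""

    for raw in content.splitlines():
        lineno += 1
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if line.startswith("# text"):
                _, _, val = line.partition("=")
                cur_text = val.strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluError(f"line {lineno}: expected 10 columns, got {len(cols)}")
        tid, form, lemma, upos, xpos, feats, head, deprel, deps, misc = cols
        if "-" in tid or "." in tid:
            continue  # multiword-token and empty-node lines carry no parse row
        if head in ("", "_"):
            raise ConlluError(f"line {lineno}: missing HEAD column")
        try:
            head_i = int(head)
        except ValueError as exc:
            raise ConlluError(f"line {lineno}: malformed HEAD {head!r}") from exc
        pos = xpos if xpos not in ("", "_") else upos
        lem = lemma if lemma not in ("", "_") else form.lower()
        cur_rows.append((form, lem, pos, head_i, deprel))
    flush()

    if not sentences:
        raise ConlluError("no sentences")
    return Document(text="\n".join(doc_text_parts), sentences=sentences, doc_id=doc_id)


def write_conllu(doc: Document) -> str:
    """Serialize a Document's sentences/tokens/edges as CoNLL-U text."""
    out = []
    for sent in doc.sentences:
        out.append(f"# text = {doc.slice(sent.span)}")
        heads = {}
        labels = {}
        for e in sent.graph:
            heads[e.dependent] = e.governor + 1
            labels[e.dependent] = e.label
        for t in sent.tokens:
            head = heads.get(t.index, 0)
            deprel = labels.get(t.index, "root" if head == 0 else "dep")
            out.append(
                "\t".join(
                    [
                        str(t.index + 1),
                        t.text,
                        t.lemma,
                        t.pos,
                        t.pos,
                        "_",
                        str(head),
                        deprel,
                        "_",
                        "_",
                    ]
                )
            )
        out.append("")
    return "\n".join(out) + "\n"
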