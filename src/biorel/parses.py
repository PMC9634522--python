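"""Pre-parsed sentence records and their attachment to documents.

The artifact does not run a sentence splitter or parser itself; it
consumes the output of an external preprocessing pipeline as a sidecar
file in a CoNLL-U-like format, one token per line::

    # doc_id = <document stem>
    1\tThe\t_\tDT\t_\t_\t2\tdet\t_\tstart=0|end=3
    2\tpercentage\t_\tNN\t_\t_\t0\troot\t_\tstart=4|end=14

Columns: index (1-based within the sentence), form, lemma (unused),
POS, xpos (unused), feats (unused), head (0 = root), dependency
relation, deps (unused), MISC carrying ``start=``/``end=`` character
offsets into the raw document text (0-based, half-open).  Sentences are
separated by blank lines; a ``# doc_id`` comment starts each document's
block.  Offsets are validated against the document text on attachment,
which rejects 1-based (or otherwise shifted) offset conventions loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .standoff import Document, StandoffIntegrityError


@dataclass(frozen=True)
class Token:
    word: str
    pos: str
    char_start: int
    char_end: int


@dataclass
class SentenceGraph:
    """Tokens plus labeled dependency edges for one sentence.

    ``edges`` holds ``(head index, dependent index, dependency type)``
    with sentence-local 0-based token indices; the root attachment
    (head 0 in CoNLL) produces no edge.
    """

    tokens: list[Token]
    edges: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def sent_start(self) -> int:
        return self.tokens[0].char_start

    @property
    def sent_end(self) -> int:
        return self.tokens[-1].char_end

    def validate(self) -> None:
        prev_end = -1
        for t in self.tokens:
            if not (t.char_start < t.char_end):
                raise ValueError(f"empty token span {t}")
            if t.char_start < prev_end:
                raise ValueError(f"token offsets overlap or decrease at {t}")
            prev_end = t.char_end
        n = len(self.tokens)
        for h, d, _lab in self.edges:
            if not (0 <= h < n and 0 <= d < n):
                raise ValueError(f"edge ({h},{d}) outside 0..{n - 1}")


class ParseFormatError(Exception):
    pass


def _parse_misc(misc: str, line_no: int) -> tuple[int, int]:
    kv = {}
    for item in misc.split("|"):
        if "=" in item:
            k, v = item.split("=", 1)
            kv[k] = v
    try:
        return int(kv["start"]), int(kv["end"])
    except (KeyError, ValueError):
        raise ParseFormatError(f"line {line_no}: MISC must carry start=/end= offsets")


def read_parses(content: str) -> dict[str, list[SentenceGraph]]:
    """Parse a sidecar file into per-document sentence lists."""
    out: dict[str, list[SentenceGraph]] = {}
    doc_id = None
    tokens: list[Token] = []
    heads: list[int] = []
    deprels: list[str] = []

    def flush():
        nonlocal tokens, heads, deprels
        if tokens:
            if doc_id is None:
                raise ParseFormatError("sentence before any '# doc_id =' header")
            edges = [
                (h - 1, i, lab)
                for i, (h, lab) in enumerate(zip(heads, deprels))
                if h > 0
            ]
            sg = SentenceGraph(tokens=tokens, edges=edges)
            sg.validate()
            out.setdefault(doc_id, []).append(sg)
        tokens, heads, deprels = [], [], []

    for line_no, raw in enumerate(content.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if "doc_id" in line and "=" in line:
                flush()
                doc_id = line.split("=", 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseFormatError(f"line {line_no}: expected 10 columns, got {len(cols)}")
        idx, form, _lemma, pos, _xpos, _feats, head, deprel, _deps, misc = cols
        if int(idx) != len(tokens) + 1:
            raise ParseFormatError(f"line {line_no}: token index {idx} out of order")
        start, end = _parse_misc(misc, line_no)
        tokens.append(Token(form, pos, start, end))
        heads.append(int(head))
        deprels.append(deprel)
    flush()
    return out


def write_parses(doc_sentences: dict[str, list[SentenceGraph]]) -> str:
    lines = []
    for doc_id, sents in doc_sentences.items():
        lines.append(f"# doc_id = {doc_id}")
        for sg in sents:
            head_of = {d: (h, lab) for h, d, lab in sg.edges}
            for i, t in enumerate(sg.tokens):
                h, lab = head_of.get(i, (-1, "root"))
                lines.append(
                    f"{i + 1}\t{t.word}\t_\t{t.pos}\t_\t_\t{h + 1}\t{lab}\t_\t"
                    f"start={t.char_start}|end={t.char_end}"
                )
            lines.append("")
    return "\n".join(lines) + "\n"


def attach_parses(doc: Document, sentences: Iterable[SentenceGraph]) -> Document:
    """Populate ``doc.sentences`` and resolve entity token spans.

    Every token's surface is checked against the document text slice at
    its offsets.  Each entity is assigned, by character overlap, the
    tokens it touches; an entity touching tokens of more than one
    sentence is flagged ``cross_sentence`` (not an error) and yields no
    token span.  Entity offsets and the text are never modified.
    """
    sentences = list(sentences)
    for sg in sentences:
        for t in sg.tokens:
            if doc.text[t.char_start : t.char_end] != t.word:
                raise StandoffIntegrityError(
                    f"{doc.doc_id}: token {t.word!r} disagrees with text slice "
                    f"{doc.text[t.char_start:t.char_end]!r} at "
                    f"[{t.char_start}, {t.char_end}) — offsets must be 0-based "
                    "half-open over the raw text"
                )
    doc.sentences = sentences
    for ent in doc.entities:
        hits: list[tuple[int, int]] = []  # (sentence idx, token idx)
        for si, sg in enumerate(sentences):
            for ti, t in enumerate(sg.tokens):
                if ent.overlaps(t.char_start, t.char_end):
                    hits.append((si, ti))
        if not hits:
            ent.token_span = None
            ent.cross_sentence = False
            continue
        sent_ids = {si for si, _ in hits}
        if len(sent_ids) > 1:
            ent.cross_sentence = True
            ent.token_span = None
        else:
            si = hits[0][0]
            tis = [ti for _, ti in hits]
            ent.cross_sentence = False
            ent.token_span = (si, min(tis), max(tis))
    return doc
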