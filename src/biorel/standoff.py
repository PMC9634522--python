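"""Reading and writing standoff-annotated corpora (.txt / .a1 / .a2).

The standoff convention stores the raw document text in a ``.txt`` file,
entity annotations ("T" lines, with character offsets into the text) in a
``.a1`` file, and binary relation annotations ("R" lines, referring to
entity ids) in a ``.a2`` file.  Character offsets are 0-based, half-open,
over the raw text including newlines.

Two relation-argument dialects are accepted on input:

* positional — ``R1\tLives_In Arg1:T1 Arg2:T2``
* role-named — ``R1\tLives_In Microorganism:T1 Location:T2``

Output uses the role names declared in the task configuration when one is
given, otherwise ``Arg1``/``Arg2``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger(__name__)


class StandoffError(Exception):
    """Base class for standoff I/O problems."""


class StandoffParseError(StandoffError):
    """A malformed annotation line; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class StandoffIntegrityError(StandoffError):
    """Annotation disagrees with the document text (offset/surface mismatch)."""


class DanglingReferenceError(StandoffError):
    """A relation argument id does not resolve to any entity."""


@dataclass
class Entity:
    """An annotated text span with an entity type.

    ``token_span`` is filled by parse attachment: ``(sentence index,
    first token index, last token index)`` — token indices are
    sentence-local and inclusive.  ``cross_sentence`` marks entities whose
    character span overlaps tokens in more than one sentence; such
    entities cannot anchor an intra-sentence candidate pair.
    """

    id: str
    etype: str
    char_start: int
    char_end: int
    surface: str
    token_span: Optional[tuple[int, int, int]] = None
    cross_sentence: bool = False

    def overlaps(self, start: int, end: int) -> bool:
        return self.char_start < end and start < self.char_end


@dataclass
class RelationAnnotation:
    """A binary relation between two entities of the same document."""

    id: str
    rtype: str
    arg1_id: str
    arg2_id: str

    def pair(self) -> frozenset:
        return frozenset((self.arg1_id, self.arg2_id))


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    sentences: list = field(default_factory=list)  # list[SentenceGraph]

    def entity_by_id(self, eid: str) -> Entity:
        for e in self.entities:
            if e.id == eid:
                return e
        raise DanglingReferenceError(f"{self.doc_id}: no entity {eid!r}")


_A1_RE = re.compile(r"^(T\d+)\t(\S+) (.+?)\t(.*)$", re.S)
_A2_RE = re.compile(r"^(R\d+)\t(\S+) ([^:\s]+):(T\d+) ([^:\s]+):(T\d+)\s*$")


def read_standoff(
    txt_content: str,
    a1_content: str,
    a2_content: Optional[str] = None,
    doc_id: str = "doc",
) -> Document:
    """Parse a document from its text and annotation file contents.

    Discontinuous entity spans (``start end;start end``) are collapsed to
    their envelope with a warning; the surface check is skipped for them.
    """
    doc = Document(doc_id=doc_id, text=txt_content)
    seen_ids: set[str] = set()
    for line_no, raw in enumerate(a1_content.splitlines(), start=1):
        if not raw.strip():
            continue
        if not raw.startswith("T"):
            # normalization (N) / note (#) lines are legal but out of scope
            continue
        m = _A1_RE.match(raw)
        if m is None:
            raise StandoffParseError(f"malformed entity line {raw!r}", line_no)
        eid, etype, span_field, surface = m.groups()
        if eid in seen_ids:
            raise StandoffParseError(f"duplicate entity id {eid}", line_no)
        seen_ids.add(eid)
        fragments = []
        for frag in span_field.split(";"):
            parts = frag.split()
            if len(parts) != 2 or not all(p.isdigit() for p in parts):
                raise StandoffParseError(f"bad offsets {span_field!r}", line_no)
            fragments.append((int(parts[0]), int(parts[1])))
        start = min(f[0] for f in fragments)
        end = max(f[1] for f in fragments)
        if start >= end:
            raise StandoffParseError(f"empty span {start}..{end}", line_no)
        discontinuous = len(fragments) > 1
        if discontinuous:
            log.warning(
                "%s %s: discontinuous span collapsed to envelope [%d, %d)",
                doc_id, eid, start, end,
            )
        if end > len(txt_content):
            raise StandoffIntegrityError(
                f"{doc_id} {eid}: offset {end} beyond text length {len(txt_content)}"
            )
        if not discontinuous and txt_content[start:end] != surface:
            raise StandoffIntegrityError(
                f"{doc_id} {eid}: surface {surface!r} != text slice "
                f"{txt_content[start:end]!r} at [{start}, {end})"
            )
        doc.entities.append(Entity(eid, etype, start, end, txt_content[start:end]))

    if a2_content:
        ids = {e.id for e in doc.entities}
        for line_no, raw in enumerate(a2_content.splitlines(), start=1):
            if not raw.strip() or raw.startswith(("*", "#")):
                continue
            m = _A2_RE.match(raw)
            if m is None:
                raise StandoffParseError(f"malformed relation line {raw!r}", line_no)
            rid, rtype, _role1, t1, _role2, t2 = m.groups()
            for t in (t1, t2):
                if t not in ids:
                    raise DanglingReferenceError(
                        f"{doc_id} {rid}: argument {t} not in .a1"
                    )
            doc.relations.append(RelationAnnotation(rid, rtype, t1, t2))
    return doc


def _roles_for(rtype: str, task=None) -> tuple[str, str]:
    if task is not None and rtype in getattr(task, "roles", {}):
        return tuple(task.roles[rtype])
    return ("Arg1", "Arg2")


def _orient_args(doc: Document, rel: RelationAnnotation, task) -> tuple[str, str]:
    """Put the priority-typed entity (e.g. the microorganism) in first position."""
    if task is None or not getattr(task, "orientation_priority", None):
        return rel.arg1_id, rel.arg2_id
    prio = {t: i for i, t in enumerate(task.orientation_priority)}
    e1 = doc.entity_by_id(rel.arg1_id)
    e2 = doc.entity_by_id(rel.arg2_id)
    r1 = prio.get(e1.etype, len(prio))
    r2 = prio.get(e2.etype, len(prio))
    if r2 < r1:
        return rel.arg2_id, rel.arg1_id
    return rel.arg1_id, rel.arg2_id


def write_a1(doc: Document) -> str:
    lines = [
        f"{e.id}\t{e.etype} {e.char_start} {e.char_end}\t{e.surface}"
        for e in doc.entities
    ]
    return "".join(line + "\n" for line in lines)


def write_a2(doc: Document, relations: Iterable[RelationAnnotation], task=None) -> str:
    lines = []
    for rel in relations:
        role1, role2 = _roles_for(rel.rtype, task)
        a1, a2 = _orient_args(doc, rel, task)
        lines.append(f"{rel.id}\t{rel.rtype} {role1}:{a1} {role2}:{a2}")
    return "".join(line + "\n" for line in lines)


def write_predictions(
    doc: Document, predicted: Iterable[RelationAnnotation], task=None
) -> str:
    """Serialise predicted relations as .a2 content, ids renumbered from R1.

    Predictions labelled ``none`` must not be passed in; relation
    categories are validated against the task configuration when given.
    """
    out = []
    for i, rel in enumerate(predicted, start=1):
        if task is not None and rel.rtype not in task.categories:
            raise ValueError(f"unknown relation category {rel.rtype!r}")
        if rel.rtype == "none":
            raise ValueError("'none' predictions must be filtered before writing")
        for t in (rel.arg1_id, rel.arg2_id):
            doc.entity_by_id(t)  # raises DanglingReferenceError
        out.append(RelationAnnotation(f"R{i}", rel.rtype, rel.arg1_id, rel.arg2_id))
    return write_a2(doc, out, task)


def read_corpus_dir(path, task=None) -> list[Document]:
    """Read every ``<stem>.txt`` (+ optional .a1/.a2) under a directory."""
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        stem = txt.stem
        a1 = txt.with_suffix(".a1")
        a2 = txt.with_suffix(".a2")
        docs.append(
            read_standoff(
                txt.read_text(),
                a1.read_text() if a1.exists() else "",
                a2.read_text() if a2.exists() else None,
                doc_id=stem,
            )
        )
    return docs


def write_corpus_dir(docs: Iterable[Document], path, task=None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.doc_id}.txt").write_text(doc.text)
        (path / f"{doc.doc_id}.a1").write_text(write_a1(doc))
        (path / f"{doc.doc_id}.a2").write_text(write_a2(doc, doc.relations, task))
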