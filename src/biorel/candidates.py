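"""Candidate-instance construction.

Every unordered pair of entities that (a) lie in the same sentence and
(b) have a type pair occurring in at least one legal constraint triple
becomes one classification instance.  Pairs carrying a gold annotation
keep their category; all other pairs are labelled ``none`` (negative
instances).  Gold relations whose entities sit in different sentences
produce no instance — only intra-sentence relations are modelled — and
are later charged to the system as recall misses by the evaluator.

Each instance also carries the per-token feature sequences that feed
the encoder: the entity-type chain (-1 on non-entity tokens) and two
signed token-distance chains, one per candidate entity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .deppath import (
    ShortestPath,
    build_undirected_graph,
    connected,
    entity_head_token,
    orient_path,
    shortest_dependency_path,
)
from .parses import SentenceGraph
from .standoff import Document, Entity
from .task import ConstraintRule

log = logging.getLogger(__name__)


@dataclass
class CandidateInstance:
    """One (sentence, entity pair) unit to classify.

    ``e1``/``e2`` are stored in sentence order; path orientation is the
    business of the dependency-feature stage.  ``entity_type_seq`` has
    one entry per sentence token (-1 on non-entity tokens, the type
    name otherwise); ``dist1_seq``/``dist2_seq`` hold signed token
    distances from each token to the nearest token of each entity.
    """

    doc_id: str
    sent_index: int
    e1: Entity
    e2: Entity
    label: str
    sentence: SentenceGraph
    entity_type_seq: list = field(default_factory=list)
    dist1_seq: list = field(default_factory=list)
    dist2_seq: list = field(default_factory=list)
    sdp: Optional[ShortestPath] = None

    @property
    def is_positive(self) -> bool:
        return self.label != "none"

    def pair_key(self) -> tuple:
        return (self.doc_id, frozenset((self.e1.id, self.e2.id)))


def _type_sequence(sent: SentenceGraph, entities: Sequence[Entity]) -> list:
    seq: list = [-1] * len(sent.tokens)
    for ent in entities:
        _si, t0, t1 = ent.token_span
        for t in range(t0, t1 + 1):
            seq[t] = ent.etype
    return seq


def _distance_sequence(sent: SentenceGraph, ent: Entity) -> list[int]:
    """Signed token distance from each token to the entity's nearest token."""
    _si, t0, t1 = ent.token_span
    out = []
    for i in range(len(sent.tokens)):
        if i < t0:
            out.append(i - t0)
        elif i > t1:
            out.append(i - t1)
        else:
            out.append(0)
    return out


def enumerate_candidates(
    doc: Document, rules: ConstraintRule
) -> list[CandidateInstance]:
    """Enumerate labelled intra-sentence candidate pairs for one document.

    A pair annotated with a category that is illegal for its entity
    types is kept with its gold label (the corpus is trusted over the
    constraint table) but logged.  A pair with gold relations in two
    categories yields one instance per category.  Self-pairs and
    duplicate entities at identical offsets are excluded.
    """
    if not doc.sentences:
        raise ValueError(f"{doc.doc_id}: sentences not attached")
    gold: dict[frozenset, list[str]] = {}
    for rel in doc.relations:
        gold.setdefault(rel.pair(), []).append(rel.rtype)

    by_sentence: dict[int, list[Entity]] = {}
    for ent in doc.entities:
        if ent.token_span is None:
            continue
        by_sentence.setdefault(ent.token_span[0], []).append(ent)

    instances: list[CandidateInstance] = []
    for si, ents in sorted(by_sentence.items()):
        sent = doc.sentences[si]
        ents = sorted(ents, key=lambda e: (e.char_start, e.char_end, e.id))
        for i in range(len(ents)):
            for j in range(i + 1, len(ents)):
                e1, e2 = ents[i], ents[j]
                if (e1.char_start, e1.char_end) == (e2.char_start, e2.char_end):
                    continue  # duplicate span cannot carry a relation
                if not rules.pair_is_legal(e1.etype, e2.etype):
                    continue
                labels = gold.get(frozenset((e1.id, e2.id)), ["none"])
                for label in labels:
                    if label != "none" and not rules.triple_is_legal(
                        e1.etype, e2.etype, label
                    ):
                        log.warning(
                            "%s: gold %s between (%s, %s) violates constraints; kept",
                            doc.doc_id, label, e1.etype, e2.etype,
                        )
                    instances.append(
                        CandidateInstance(
                            doc_id=doc.doc_id,
                            sent_index=si,
                            e1=e1,
                            e2=e2,
                            label=label,
                            sentence=sent,
                            entity_type_seq=_type_sequence(sent, (e1, e2)),
                            dist1_seq=_distance_sequence(sent, e1),
                            dist2_seq=_distance_sequence(sent, e2),
                        )
                    )
    return instances


def attach_paths(
    instances: Sequence[CandidateInstance], rules: ConstraintRule
) -> list[CandidateInstance]:
    """Compute and orient the shortest dependency path of each instance.

    Instances in disconnected parse components keep ``sdp=None`` and
    are removed by :func:`filter_no_path`.
    """
    graphs: dict[int, dict] = {}
    for inst in instances:
        g = graphs.get(id(inst.sentence))
        if g is None:
            g = build_undirected_graph(inst.sentence)
            graphs[id(inst.sentence)] = g
        h1 = entity_head_token(inst.e1)
        h2 = entity_head_token(inst.e2)
        if h1 == h2:
            inst.sdp = None  # degenerate overlap: no usable path
            continue
        path = shortest_dependency_path(g, h1, h2, inst.sentence)
        if path is not None:
            path = orient_path(path, inst.e1, inst.e2, rules)
        inst.sdp = path
    return list(instances)


def filter_no_path(
    instances: Sequence[CandidateInstance],
) -> list[CandidateInstance]:
    """Drop instances whose entities have no dependency path between them."""
    graphs: dict[int, dict] = {}
    kept = []
    removed = 0
    for inst in instances:
        g = graphs.get(id(inst.sentence))
        if g is None:
            g = build_undirected_graph(inst.sentence)
            graphs[id(inst.sentence)] = g
        h1 = entity_head_token(inst.e1)
        h2 = entity_head_token(inst.e2)
        if h1 != h2 and connected(g, h1, h2):
            kept.append(inst)
        else:
            removed += 1
    if removed:
        log.info("filter_no_path: removed %d of %d instances", removed, len(instances))
    return kept


def subsample_negatives(
    instances: Sequence[CandidateInstance], keep_fraction: float, seed: int
) -> list[CandidateInstance]:
    """Randomly delete a fraction of the negative instances (training only).

    Exactly ``floor((1 - keep_fraction) * N_neg)`` negatives are removed
    uniformly at random; every positive is kept; original order is
    preserved.  Deterministic given ``seed``.
    """
    if not (0.0 <= keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in [0, 1], got {keep_fraction}")
    neg_positions = [i for i, inst in enumerate(instances) if not inst.is_positive]
    n_delete = math.floor((1.0 - keep_fraction) * len(neg_positions))
    rng = np.random.default_rng(seed)
    doomed = set(
        rng.choice(len(neg_positions), size=n_delete, replace=False).tolist()
    )
    doomed_positions = {neg_positions[k] for k in doomed}
    return [inst for i, inst in enumerate(instances) if i not in doomed_positions]


def instance_to_dict(inst: CandidateInstance) -> dict:
    """JSON-serialisable summary of one instance (for JSON-lines dumps)."""
    d = {
        "doc_id": inst.doc_id,
        "sent_index": inst.sent_index,
        "e1": inst.e1.id,
        "e2": inst.e2.id,
        "label": inst.label,
        "entity_type_seq": inst.entity_type_seq,
        "dist1_seq": inst.dist1_seq,
        "dist2_seq": inst.dist2_seq,
    }
    if inst.sdp is not None:
        d["sdp_tokens"] = list(inst.sdp.token_seq)
        d["sdp_deptypes"] = list(inst.sdp.deptype_seq)
    return d


def corpus_statistics(instances: Sequence[CandidateInstance]) -> dict[str, int]:
    """Per-category instance counts plus ``total`` (the printed-table shape)."""
    counts: dict[str, int] = {}
    for inst in instances:
        counts[inst.label] = counts.get(inst.label, 0) + 1
    counts["total"] = len(instances)
    return counts
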