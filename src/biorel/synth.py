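"""Synthetic standoff corpora with plantable relation signal.

The generator emulates the statistical shape of the shared-task data —
dominant negative pairs, intra-sentence relations, short dependency
paths — without any linguistic realism.  Each sentence gets a random
dependency tree over Zipf-distributed pseudo-words, entities are placed
on tokens with types from the task inventory, and a legal entity pair
is made positive according to a planting rule:

* ``trigger_on_sdp`` — positive iff a trigger lemma sits on the
  dependency path between the two entities (the default; negatives may
  receive an off-path decoy trigger so that trigger *presence* alone
  carries no label information);
* ``sdp_length``     — positive iff the path has at most ``max_sdp_length``
  tokens;
* ``type_pair``      — positive with a per-type-pair probability.

``noise_rate`` is the probability that a planted positive lacks its
signal.  Everything is deterministic given the seed.  ``forest_rate``
optionally detaches part of a sentence's tree into a second component
so that path-less pairs exist (exercising the no-path filter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .parses import SentenceGraph, Token, attach_parses, write_parses
from .standoff import Document, Entity, RelationAnnotation, write_a1, write_a2
from .task import ConstraintRule, load_task

DEPREL_SET = ("nsubj", "dobj", "amod", "det", "prep_of", "advmod", "nmod", "conj")
POS_SET = ("NN", "VB", "JJ", "DT", "IN", "RB")


@dataclass
class SynthConfig:
    seed: int = 0
    n_documents: int = 200
    sentences_per_doc: tuple[int, int] = (2, 3)
    sentence_length: tuple[int, int] = (8, 14)
    entity_count: tuple[int, int] = (2, 2)
    vocab_size: int = 200
    positive_rate: float = 0.5
    noise_rate: float = 0.05
    decoy_rate: float = 0.5
    signal: str = "trigger_on_sdp"
    max_sdp_length: int = 4
    forest_rate: float = 0.0
    trigger_words: tuple[str, ...] = ("trigrel",)
    task: str = "bbrel"

    def __post_init__(self):
        for p in (self.positive_rate, self.noise_rate, self.decoy_rate,
                  self.forest_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.signal not in ("trigger_on_sdp", "sdp_length", "type_pair"):
            raise ValueError(f"unknown planting rule {self.signal!r}")


@dataclass
class CorpusBundle:
    documents: list[Document]
    parses: dict[str, list[SentenceGraph]]
    manifest: dict
    task: ConstraintRule


def _zipf_lexicon(rng: np.random.Generator, size: int):
    words = [f"w{i:03d}" for i in range(size)]
    p = 1.0 / np.arange(1, size + 1) ** 1.1
    return words, p / p.sum()


def _random_tree(rng: np.random.Generator, n: int, forest: bool):
    """Random-attachment dependency tree (or two-component forest)."""
    heads = [-1] * n
    cut = n // 2 if (forest and n >= 6) else None
    for i in range(1, n):
        if cut is not None and i == cut:
            continue  # second root
        lo = cut if (cut is not None and i > cut) else 0
        heads[i] = int(rng.integers(lo, i))
    edges = [
        (h, i, DEPREL_SET[int(rng.integers(len(DEPREL_SET)))])
        for i, h in enumerate(heads)
        if h >= 0
    ]
    return heads, edges


def _tree_path(heads: list[int], a: int, b: int) -> Optional[list[int]]:
    """Token path a..b through the (forest) tree, or None if disconnected."""
    anc_a = []
    x = a
    while x != -1:
        anc_a.append(x)
        x = heads[x]
    pos = {t: i for i, t in enumerate(anc_a)}
    x = b
    up_b = []
    while x != -1 and x not in pos:
        up_b.append(x)
        x = heads[x]
    if x == -1:
        return None
    return anc_a[: pos[x] + 1] + up_b[::-1]


def _legal_category(task: ConstraintRule, ta: str, tb: str) -> Optional[str]:
    for cat in task.positive_categories:
        if task.triple_is_legal(ta, tb, cat):
            return cat
    return None if task.legal_triples is not None else task.positive_categories[0]


def generate_corpus(config: SynthConfig) -> CorpusBundle:
    """Generate documents, parse sidecars and a ground-truth manifest."""
    task = load_task(config.task)
    if not task.entity_types:
        raise ValueError("task entity-type inventory is empty")
    rng = np.random.default_rng(config.seed)
    lexicon, lex_p = _zipf_lexicon(rng, config.vocab_size)

    documents: list[Document] = []
    parses: dict[str, list[SentenceGraph]] = {}
    n_pos = 0
    n_neg = 0
    n_no_path = 0
    n_plantable = 0
    sdp_hist: dict[int, int] = {}
    cat_counts: dict[str, int] = {}

    for di in range(config.n_documents):
        doc_id = f"synth-{di:04d}"
        n_sents = int(rng.integers(config.sentences_per_doc[0],
                                   config.sentences_per_doc[1] + 1))
        sent_graphs: list[SentenceGraph] = []
        entities: list[Entity] = []
        relations: list[RelationAnnotation] = []
        text_parts: list[str] = []
        offset = 0
        ent_id = 1
        rel_id = 1
        for _si in range(n_sents):
            n = int(rng.integers(config.sentence_length[0],
                                 config.sentence_length[1] + 1))
            words = list(rng.choice(lexicon, size=n, p=lex_p))
            pos_tags = list(rng.choice(POS_SET, size=n))
            forest = bool(rng.random() < config.forest_rate)
            heads, edges = _random_tree(rng, n, forest)

            k = min(int(rng.integers(config.entity_count[0],
                                     config.entity_count[1] + 1)), n // 2)
            positions = sorted(rng.choice(n, size=k, replace=False).tolist())
            types = [
                task.entity_types[int(rng.integers(len(task.entity_types)))]
                for _ in range(k)
            ]
            if task.orientation_priority and k > 0:
                # anchor one priority-type entity so legal pairs are common
                types[int(rng.integers(k))] = task.orientation_priority[0]
            ent_local = []
            for pi, (tok_i, et) in enumerate(zip(positions, types)):
                words[tok_i] = f"{et[:4]}{int(rng.integers(100))}"
                pos_tags[tok_i] = "NN"
                ent_local.append((tok_i, et))

            # decide labels pair by pair, claiming trigger slots as we go
            pair_paths = {}
            for i in range(k):
                for j in range(i + 1, k):
                    pair_paths[(i, j)] = _tree_path(
                        heads, ent_local[i][0], ent_local[j][0]
                    )
            on_any_path = {
                t for p in pair_paths.values() if p for t in p
            }
            entity_tokens = {t for t, _ in ent_local}
            planted: list[tuple[int, int, str]] = []
            order = [list(pair_paths)[i] for i in rng.permutation(len(pair_paths))]
            claimed: set[int] = set()
            for (i, j) in order:
                ti, tj = ent_local[i][1], ent_local[j][1]
                if not task.pair_is_legal(ti, tj):
                    continue
                cat = _legal_category(task, ti, tj)
                path = pair_paths[(i, j)]
                if path is None:
                    n_no_path += 1
                    continue
                interior = [t for t in path if t not in entity_tokens]
                positive = False
                if config.signal == "trigger_on_sdp":
                    # a trigger may only sit on tokens exclusive to this
                    # pair's path, so it never leaks onto another pair's
                    # SDP; pairs without such a slot stay negative
                    others = {
                        t
                        for key, p in pair_paths.items()
                        if p is not None and key != (i, j)
                        for t in p
                    }
                    free = [
                        t for t in interior if t not in others and t not in claimed
                    ]
                    if free:
                        n_plantable += 1
                    if free and rng.random() < config.positive_rate:
                        positive = True
                        if rng.random() >= config.noise_rate:
                            spot = free[int(rng.integers(len(free)))]
                            words[spot] = config.trigger_words[
                                int(rng.integers(len(config.trigger_words)))
                            ]
                            claimed.add(spot)
                    if not positive and rng.random() < config.decoy_rate:
                        off = [
                            t for t in range(n)
                            if t not in on_any_path and t not in entity_tokens
                            and t not in claimed
                        ]
                        if off:
                            spot = off[int(rng.integers(len(off)))]
                            words[spot] = config.trigger_words[
                                int(rng.integers(len(config.trigger_words)))
                            ]
                            claimed.add(spot)
                elif config.signal == "sdp_length":
                    short = len(path) <= config.max_sdp_length
                    positive = short != (rng.random() < config.noise_rate)
                else:  # type_pair
                    positive = rng.random() < config.positive_rate
                if positive:
                    planted.append((i, j, cat))
                    n_pos += 1
                    cat_counts[cat] = cat_counts.get(cat, 0) + 1
                else:
                    n_neg += 1
                sdp_hist[len(path)] = sdp_hist.get(len(path), 0) + 1

            # materialise the sentence text
            starts = []
            for w in words:
                starts.append(offset)
                offset += len(w) + 1
            tokens = [
                Token(w, p, s, s + len(w))
                for w, p, s in zip(words, pos_tags, starts)
            ]
            sg = SentenceGraph(tokens=tokens, edges=edges)
            sg.validate()
            sent_graphs.append(sg)
            text_parts.append(" ".join(words))

            local_ids = {}
            for tok_i, et in ent_local:
                t = tokens[tok_i]
                eid = f"T{ent_id}"
                ent_id += 1
                entities.append(Entity(eid, et, t.char_start, t.char_end, t.word))
                local_ids[tok_i] = eid
            for (i, j, cat) in planted:
                relations.append(
                    RelationAnnotation(
                        f"R{rel_id}", cat,
                        local_ids[ent_local[i][0]], local_ids[ent_local[j][0]],
                    )
                )
                rel_id += 1

        text = " ".join(text_parts) + "\n"
        doc = Document(doc_id=doc_id, text=text, entities=entities,
                       relations=relations)
        attach_parses(doc, sent_graphs)
        documents.append(doc)
        parses[doc_id] = sent_graphs

    manifest = {
        "seed": config.seed,
        "n_documents": config.n_documents,
        "n_positive_pairs": n_pos,
        "n_negative_pairs": n_neg,
        "n_no_path_pairs": n_no_path,
        "n_plantable_pairs": n_plantable,
        "category_counts": dict(sorted(cat_counts.items())),
        "sdp_length_histogram": {str(k): v for k, v in sorted(sdp_hist.items())},
    }
    return CorpusBundle(documents=documents, parses=parses,
                        manifest=manifest, task=task)


def write_corpus(bundle: CorpusBundle, out_dir) -> None:
    """Write .txt/.a1/.a2 files, the parse sidecar, and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in bundle.documents:
        (out / f"{doc.doc_id}.txt").write_text(doc.text)
        (out / f"{doc.doc_id}.a1").write_text(write_a1(doc))
        (out / f"{doc.doc_id}.a2").write_text(
            write_a2(doc, doc.relations, bundle.task)
        )
    (out / "parses.conll").write_text(write_parses(bundle.parses))
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def generate_embeddings(
    words, d: int, seed: int
) -> tuple[list[str], np.ndarray]:
    """Random unit-norm word vectors (a stand-in pretrained table)."""
    if d <= 0:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(seed)
    words = list(words)
    mat = rng.standard_normal((len(words), d)).astype(np.float32)
    mat /= np.linalg.norm(mat, axis=1, keepdims=True)
    return words, mat
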