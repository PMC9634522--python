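"""Numeric feature encoding of candidate instances.

Each sentence token is represented by the concatenation of five
channels: word embedding (200, with a sinusoidal position encoding
added), POS embedding (200), entity-type embedding (200), and two
relative-distance embeddings (100 each, sharing one table) — 800
dimensions per token in the default configuration.  The shortest
dependency path gets its own channel: word embedding (200) next to
dependency-type embedding (200), the type sequence padded by one row to
the path length.

Word vectors may be initialised from a word2vec text-format table; the
most frequent ``k`` words build the dictionary, one placeholder word
per entity type is added (an entity word missing from the dictionary is
replaced by its type placeholder at lookup), and everything else is
randomly initialised under the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .candidates import CandidateInstance

PAD = 0
UNK = 1

DEFAULT_DIMS = {
    "word": 200,
    "pos": 200,
    "etype": 200,
    "dist": 100,
    "deptype": 200,
}


class EmbeddingFormatError(Exception):
    pass


def read_word2vec_text(path) -> tuple[list[str], np.ndarray]:
    """Read a word2vec text-format table: header 'V d', then word + d floats."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise EmbeddingFormatError("empty embedding file")
    head = lines[0].split()
    if len(head) != 2 or not all(p.isdigit() for p in head):
        raise EmbeddingFormatError(f"bad header {lines[0]!r}: expected 'V d'")
    v, d = int(head[0]), int(head[1])
    words, rows = [], []
    for i, line in enumerate(lines[1 : v + 1], start=2):
        parts = line.rstrip().split(" ")
        if len(parts) != d + 1:
            raise EmbeddingFormatError(f"line {i}: expected {d + 1} fields")
        words.append(parts[0])
        rows.append(np.asarray(parts[1:], dtype=np.float32))
    if len(words) != v:
        raise EmbeddingFormatError(f"header declared {v} rows, found {len(words)}")
    return words, np.stack(rows)


def write_word2vec_text(words: Sequence[str], matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(words)} {matrix.shape[1]}\n")
        for w, row in zip(words, matrix):
            fh.write(w + " " + " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class Vocabulary:
    """Token dictionary with PAD/UNK specials and per-entity-type placeholders."""

    word2idx: dict[str, int]
    placeholders: dict[str, int]  # entity type -> index
    itos: list[str]

    def __len__(self) -> int:
        return len(self.itos)

    def lookup(self, word: str, etype=None) -> int:
        """Index of ``word``; an unknown entity word falls back to its
        type placeholder, any other unknown word to UNK."""
        idx = self.word2idx.get(word)
        if idx is not None:
            return idx
        if etype is not None and etype in self.placeholders:
            return self.placeholders[etype]
        return UNK


def build_vocabulary(
    embedding_source: Optional[tuple[Sequence[str], np.ndarray]],
    entity_types: Sequence[str],
    k: int,
    corpus_tokens: Optional[Sequence[str]] = None,
    seed: int = 0,
    d_word: int = DEFAULT_DIMS["word"],
) -> tuple[Vocabulary, np.ndarray]:
    """Build the word dictionary and its (initial) embedding matrix.

    With an embedding source, its first ``k`` words (the table is
    assumed frequency-ordered, as word2vec writes it) enter the
    dictionary with their pretrained vectors.  Without one, the ``k``
    most frequent corpus tokens enter with random vectors.  Specials
    (PAD, UNK) and one placeholder per entity type are always present
    and randomly initialised (PAD stays zero and is never updated).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    itos = ["<pad>", "<unk>"]
    pretrained: dict[str, np.ndarray] = {}
    if embedding_source is not None:
        src_words, src_mat = embedding_source
        if src_mat.shape[1] != d_word:
            raise EmbeddingFormatError(
                f"embedding width {src_mat.shape[1]} != configured d_word {d_word}"
            )
        for w, row in list(zip(src_words, src_mat))[:k]:
            pretrained[w] = row
        vocab_words = [w for w in src_words[:k]]
    else:
        if corpus_tokens is None:
            raise ValueError("need an embedding source or corpus tokens")
        freq: dict[str, int] = {}
        for t in corpus_tokens:
            freq[t] = freq.get(t, 0) + 1
        vocab_words = [
            w for w, _c in sorted(freq.items(), key=lambda wc: (-wc[1], wc[0]))[:k]
        ]
    placeholders = {}
    for et in entity_types:
        if et not in vocab_words:
            vocab_words.append(et)
    word2idx = {}
    for w in itos:
        word2idx[w] = len(word2idx)
    for w in vocab_words:
        word2idx[w] = len(word2idx)
        itos.append(w)
    for et in entity_types:
        placeholders[et] = word2idx[et]

    table = rng.uniform(-0.05, 0.05, size=(len(itos), d_word)).astype(np.float32)
    table[PAD] = 0.0
    for w, row in pretrained.items():
        table[word2idx[w]] = row
    vocab = Vocabulary(word2idx=word2idx, placeholders=placeholders, itos=itos)
    return vocab, table


def relative_distance(l: int, s: int) -> float:
    """Signed relative distance l/s in [-1, 1] (s = corpus maximum distance)."""
    if s == 0:
        raise ValueError("maximum distance s must be positive")
    if abs(l) > s:
        raise ValueError(f"|l|={abs(l)} exceeds maximum distance s={s}")
    return l / s


def distance_index(l: int, s: int) -> int:
    """Bucket a signed token distance for table lookup (resolution 1/s).

    Distances are clipped to [-s, s]; index 0 is PAD, so the table has
    2s + 2 rows.
    """
    if s <= 0:
        raise ValueError("maximum distance s must be positive")
    l = max(-s, min(s, l))
    return l + s + 1


def positional_encoding(n: int, d: int) -> np.ndarray:
    """Sinusoidal position-encoding matrix of shape (n, d).

    PE[pos, 2i] = sin(pos / 10000^(2i/d)); PE[pos, 2i+1] = cos(same).
    """
    if d % 2 != 0:
        raise ValueError(f"dimension must be even, got {d}")
    pos = np.arange(n, dtype=np.float64)[:, None]
    i = np.arange(d // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((n, d), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


@dataclass
class FeatureSpace:
    """All index spaces needed to encode a corpus, plus initial tables.

    ``s`` is the corpus maximum absolute token distance used by the
    relative-distance buckets.  Table row 0 is PAD in every space and is
    frozen during training.
    """

    vocab: Vocabulary
    pos2idx: dict[str, int]
    etype2idx: dict[str, int]  # includes the dedicated non-entity row
    deptype2idx: dict[str, int]
    s: int
    dims: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIMS))
    word_table: Optional[np.ndarray] = None
    seed: int = 0
    unknown_counts: dict[str, int] = field(default_factory=dict)

    NON_ENTITY = 1  # etype row for the -1 marker

    def table_sizes(self) -> dict[str, int]:
        return {
            "word": len(self.vocab),
            "pos": len(self.pos2idx),
            "etype": len(self.etype2idx),
            "dist": 2 * self.s + 2,
            "deptype": len(self.deptype2idx),
        }

    def _warn_unknown(self, kind: str) -> None:
        self.unknown_counts[kind] = self.unknown_counts.get(kind, 0) + 1


def build_feature_space(
    instances: Sequence[CandidateInstance],
    entity_types: Sequence[str],
    embedding_source=None,
    k: int = 100_000,
    seed: int = 0,
    dims: Optional[dict[str, int]] = None,
) -> FeatureSpace:
    """Collect every index space from the training instances."""
    dims = dict(DEFAULT_DIMS) if dims is None else dict(dims)
    corpus_tokens = [
        t.word for inst in instances for t in inst.sentence.tokens
    ] or None
    vocab, word_table = build_vocabulary(
        embedding_source, entity_types, k,
        corpus_tokens=corpus_tokens, seed=seed, d_word=dims["word"],
    )
    pos2idx = {"<pad>": 0, "<unk>": 1}
    deptype2idx = {"<pad>": 0, "<unk>": 1}
    s = 1
    for inst in instances:
        for t in inst.sentence.tokens:
            pos2idx.setdefault(t.pos, len(pos2idx))
        for _h, _d, lab in inst.sentence.edges:
            deptype2idx.setdefault(lab, len(deptype2idx))
        for seq in (inst.dist1_seq, inst.dist2_seq):
            for l in seq:
                s = max(s, abs(l))
    etype2idx = {"<pad>": 0, "<non-entity>": FeatureSpace.NON_ENTITY}
    for et in entity_types:
        etype2idx[et] = len(etype2idx)
    return FeatureSpace(
        vocab=vocab,
        pos2idx=pos2idx,
        etype2idx=etype2idx,
        deptype2idx=deptype2idx,
        s=s,
        dims=dims,
        word_table=word_table,
        seed=seed,
    )


@dataclass
class EncodedInstance:
    """Index arrays for one candidate instance (sentence + SDP channels)."""

    word_idx: np.ndarray       # (n,)
    pos_idx: np.ndarray        # (n,)
    etype_idx: np.ndarray      # (n,)
    dist1_idx: np.ndarray      # (n,)
    dist2_idx: np.ndarray      # (n,)
    dist1_val: np.ndarray      # (n,) floats in [-1, 1]
    dist2_val: np.ndarray      # (n,)
    sdp_word_idx: np.ndarray   # (m,)
    sdp_deptype_idx: np.ndarray  # (m,) — m-1 types + one PAD row
    label: str
    label_idx: int
    n: int
    m: int
    intrasentence: bool = True
    source: Optional[CandidateInstance] = None


def encode_instance(
    inst: CandidateInstance,
    space: FeatureSpace,
    categories: Sequence[str],
) -> EncodedInstance:
    """Map a candidate instance to index arrays (a pure function of its
    inputs; unknown POS/dependency types go to the UNK row and are
    counted in the space's warning summary)."""
    sent = inst.sentence
    n = len(sent.tokens)
    word_idx = np.empty(n, dtype=np.intp)
    pos_idx = np.empty(n, dtype=np.intp)
    etype_idx = np.empty(n, dtype=np.intp)
    for i, tok in enumerate(sent.tokens):
        et = inst.entity_type_seq[i]
        word_idx[i] = space.vocab.lookup(tok.word, None if et == -1 else et)
        p = space.pos2idx.get(tok.pos)
        if p is None:
            p = UNK
            space._warn_unknown("pos")
        pos_idx[i] = p
        if et == -1:
            etype_idx[i] = FeatureSpace.NON_ENTITY
        else:
            e = space.etype2idx.get(et)
            if e is None:
                e = FeatureSpace.NON_ENTITY
                space._warn_unknown("etype")
            etype_idx[i] = e
    dist1_idx = np.array([distance_index(l, space.s) for l in inst.dist1_seq], dtype=np.intp)
    dist2_idx = np.array([distance_index(l, space.s) for l in inst.dist2_seq], dtype=np.intp)
    clip = lambda l: max(-space.s, min(space.s, l))
    dist1_val = np.array([relative_distance(clip(l), space.s) for l in inst.dist1_seq])
    dist2_val = np.array([relative_distance(clip(l), space.s) for l in inst.dist2_seq])

    if inst.sdp is None:
        raise ValueError("instance has no dependency path; run attach_paths/filter first")
    m = inst.sdp.length
    etype_at = {}
    for idx_in_path, tok_i in enumerate(inst.sdp.token_indices):
        et = inst.entity_type_seq[tok_i]
        etype_at[idx_in_path] = None if et == -1 else et
    sdp_word_idx = np.array(
        [
            space.vocab.lookup(w, etype_at[i])
            for i, w in enumerate(inst.sdp.token_seq)
        ],
        dtype=np.intp,
    )
    dep_ids = []
    for lab in inst.sdp.deptype_seq:
        d = space.deptype2idx.get(lab)
        if d is None:
            d = UNK
            space._warn_unknown("deptype")
        dep_ids.append(d)
    dep_ids.append(PAD)  # pad type chain to the path length
    sdp_deptype_idx = np.array(dep_ids, dtype=np.intp)

    cats = list(categories)
    return EncodedInstance(
        word_idx=word_idx,
        pos_idx=pos_idx,
        etype_idx=etype_idx,
        dist1_idx=dist1_idx,
        dist2_idx=dist2_idx,
        dist1_val=dist1_val,
        dist2_val=dist2_val,
        sdp_word_idx=sdp_word_idx,
        sdp_deptype_idx=sdp_deptype_idx,
        label=inst.label,
        label_idx=cats.index(inst.label),
        n=n,
        m=m,
        source=inst,
    )


def decode_instance(enc: EncodedInstance, space: FeatureSpace) -> dict:
    """Inverse lookup of the index channels (used to verify encoding)."""
    inv_pos = {v: k for k, v in space.pos2idx.items()}
    inv_et = {v: k for k, v in space.etype2idx.items()}
    return {
        "words": [space.vocab.itos[i] for i in enc.word_idx],
        "pos": [inv_pos[i] for i in enc.pos_idx],
        "etypes": [
            -1 if i == FeatureSpace.NON_ENTITY else inv_et[i] for i in enc.etype_idx
        ],
        "sdp_words": [space.vocab.itos[i] for i in enc.sdp_word_idx],
    }
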