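"""Distributed-feature encoding: distances, position encoding, vocabulary."""

import math

import numpy as np
import pytest

from biorel.candidates import attach_paths, enumerate_candidates
from biorel.encoding import (
    EmbeddingFormatError,
    build_feature_space,
    build_vocabulary,
    decode_instance,
    distance_index,
    encode_instance,
    positional_encoding,
    read_word2vec_text,
    relative_distance,
    write_word2vec_text,
)
from biorel.pipeline import preprocess_documents
from biorel.synth import SynthConfig, generate_corpus, generate_embeddings


# -- relative distance --------------------------------------------------------


def test_relative_distance_zero_and_extremes():
    assert relative_distance(0, 10) == 0.0
    assert relative_distance(10, 10) == 1.0
    assert relative_distance(-10, 10) == -1.0


def test_relative_distance_rejects_zero_s_and_overflow():
    with pytest.raises(ValueError):
        relative_distance(1, 0)
    with pytest.raises(ValueError):
        relative_distance(11, 10)


@pytest.mark.parametrize("s", [1, 7, 50])
def test_relative_distance_monotone_exhaustive(s):
    vals = [relative_distance(l, s) for l in range(-s, s + 1)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert all(-1.0 <= v <= 1.0 for v in vals)


def test_distance_index_buckets_and_clipping():
    s = 5
    assert distance_index(-5, s) == 1
    assert distance_index(0, s) == 6
    assert distance_index(5, s) == 11
    assert distance_index(99, s) == 11  # clipped
    assert distance_index(-99, s) == 1


# -- positional encoding ------------------------------------------------------


def test_pe_row_zero_alternates_zero_one():
    pe = positional_encoding(3, 8)
    assert np.allclose(pe[0, 0::2], 0.0)
    assert np.allclose(pe[0, 1::2], 1.0)


def test_pe_first_position_first_dimension_is_sin_one():
    for d in (4, 16, 200):
        pe = positional_encoding(2, d)
        assert pe[1, 0] == pytest.approx(math.sin(1.0), abs=1e-9)


def test_pe_matches_direct_elementwise_evaluation():
    n, d = 17, 12
    pe = positional_encoding(n, d)
    for pos in range(n):
        for i in range(d // 2):
            angle = pos / (10000 ** (2 * i / d))
            assert pe[pos, 2 * i] == pytest.approx(math.sin(angle), abs=1e-9)
            assert pe[pos, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-9)
    assert np.all(np.abs(pe) <= 1.0)


def test_pe_rejects_odd_dimension():
    with pytest.raises(ValueError):
        positional_encoding(4, 7)


# -- vocabulary ---------------------------------------------------------------


def test_vocabulary_from_corpus_counts_distinct_tokens():
    tokens = list("aabbccddee") + ["f", "g", "h", "i", "j"]
    vocab, table = build_vocabulary(
        None, ["Microorganism"], k=100, corpus_tokens=tokens, seed=0, d_word=8
    )
    # 10 distinct corpus tokens + PAD + UNK + 1 placeholder
    assert len(vocab) == 13
    assert table.shape == (13, 8)
    assert np.all(table[0] == 0.0)


def test_unknown_entity_word_falls_back_to_type_placeholder():
    vocab, _ = build_vocabulary(
        None, ["Microorganism", "Habitat"], k=10,
        corpus_tokens=["the", "cell"], seed=0, d_word=4,
    )
    idx = vocab.lookup("N. gonorrhoeae", etype="Microorganism")
    assert idx == vocab.placeholders["Microorganism"]
    assert vocab.lookup("N. gonorrhoeae") == 1  # UNK without type info


def test_vocabulary_random_rows_deterministic_per_seed():
    kw = dict(corpus_tokens=["a", "b"], d_word=6)
    _, t1 = build_vocabulary(None, ["Habitat"], 5, seed=9, **kw)
    _, t2 = build_vocabulary(None, ["Habitat"], 5, seed=9, **kw)
    _, t3 = build_vocabulary(None, ["Habitat"], 5, seed=10, **kw)
    assert np.array_equal(t1, t2)
    assert not np.array_equal(t1, t3)


def test_vocabulary_k_must_be_positive():
    with pytest.raises(ValueError):
        build_vocabulary(None, [], 0, corpus_tokens=["a"])


def test_pretrained_rows_are_used(tmp_path):
    words, mat = generate_embeddings(["alpha", "beta"], d=6, seed=1)
    vocab, table = build_vocabulary((words, mat), ["Habitat"], k=10, d_word=6)
    assert np.allclose(table[vocab.word2idx["alpha"]], mat[0])


def test_word2vec_text_roundtrip(tmp_path):
    words, mat = generate_embeddings([f"w{i}" for i in range(20)], d=8, seed=3)
    p = tmp_path / "emb.txt"
    write_word2vec_text(words, mat, p)
    w2, m2 = read_word2vec_text(p)
    assert w2 == words
    assert np.allclose(m2, mat, atol=1e-6)


def test_word2vec_reader_rejects_malformed(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("not a header\n")
    with pytest.raises(EmbeddingFormatError):
        read_word2vec_text(p)


# -- instance encoding --------------------------------------------------------


@pytest.fixture(scope="module")
def encoded_corpus(bbrel):
    bundle = generate_corpus(SynthConfig(seed=21, n_documents=15))
    insts = preprocess_documents(bundle.documents, bundle.task)
    space = build_feature_space(insts, bundle.task.entity_types, seed=1)
    encs = [encode_instance(i, space, bundle.task.categories) for i in insts]
    return bundle, insts, space, encs


def test_encode_decode_inverse(encoded_corpus):
    bundle, insts, space, encs = encoded_corpus
    for inst, enc in zip(insts, encs):
        dec = decode_instance(enc, space)
        assert dec["pos"] == [t.pos for t in inst.sentence.tokens]
        assert dec["etypes"] == inst.entity_type_seq
        assert dec["words"] == [t.word for t in inst.sentence.tokens]
        assert dec["sdp_words"] == list(inst.sdp.token_seq)


def test_encoding_is_pure(encoded_corpus):
    bundle, insts, space, encs = encoded_corpus
    again = encode_instance(insts[0], space, bundle.task.categories)
    assert np.array_equal(again.word_idx, encs[0].word_idx)
    assert np.array_equal(again.sdp_deptype_idx, encs[0].sdp_deptype_idx)


def test_distance_channels_swap_under_argument_swap(encoded_corpus):
    import copy

    bundle, insts, space, encs = encoded_corpus
    inst = insts[0]
    swapped = copy.copy(inst)
    swapped.e1, swapped.e2 = inst.e2, inst.e1
    swapped.dist1_seq, swapped.dist2_seq = inst.dist2_seq, inst.dist1_seq
    enc2 = encode_instance(swapped, space, bundle.task.categories)
    enc1 = encs[0]
    assert np.array_equal(enc1.dist1_idx, enc2.dist2_idx)
    assert np.array_equal(enc1.dist2_idx, enc2.dist1_idx)
    assert np.array_equal(enc1.word_idx, enc2.word_idx)
    assert np.array_equal(enc1.pos_idx, enc2.pos_idx)
    assert np.array_equal(enc1.etype_idx, enc2.etype_idx)


def test_distance_values_bounded(encoded_corpus):
    _b, _i, _s, encs = encoded_corpus
    for enc in encs:
        assert np.all(np.abs(enc.dist1_val) <= 1.0)
        assert np.all(np.abs(enc.dist2_val) <= 1.0)


def test_canonical_fixture_sdp_channel_shape_and_padding(microbe_phenotype_doc, bbrel):
    insts = enumerate_candidates(microbe_phenotype_doc, bbrel)
    attach_paths(insts, bbrel)
    space = build_feature_space(insts, bbrel.entity_types, seed=0)
    enc = encode_instance(insts[0], space, bbrel.categories)
    assert enc.m == 4
    assert enc.sdp_deptype_idx.shape == (4,)
    labels = [
        {v: k for k, v in space.deptype2idx.items()}[i] for i in enc.sdp_deptype_idx
    ]
    assert labels == ["nsubj", "prep_of", "amod", "<pad>"]
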