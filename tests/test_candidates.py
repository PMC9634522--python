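"""Candidate enumeration, constraint filtering, subsampling, statistics."""

import itertools

import numpy as np
import pytest

from biorel.candidates import (
    CandidateInstance,
    corpus_statistics,
    enumerate_candidates,
    filter_no_path,
    subsample_negatives,
)
from biorel.parses import attach_parses
from biorel.standoff import Document, Entity, RelationAnnotation
from biorel.synth import SynthConfig, generate_corpus
from biorel.task import ConstraintRule

from conftest import make_sentence


def _doc_with_entities(types, edges=None, relations=()):
    words = [f"ent{i}" for i in range(len(types))] + ["filler"]
    sent = make_sentence(words, edges or [(i + 1, i, "dobj") for i in range(len(words) - 1)])
    text = " ".join(words) + "\n"
    ents = []
    for i, et in enumerate(types):
        t = sent.tokens[i]
        ents.append(Entity(f"T{i + 1}", et, t.char_start, t.char_end, t.word))
    doc = Document("d1", text, entities=ents, relations=list(relations))
    attach_parses(doc, [sent])
    return doc


def test_unannotated_legal_pair_becomes_negative_instance(bbrel):
    doc = _doc_with_entities(["Microorganism", "Habitat"])
    (inst,) = enumerate_candidates(doc, bbrel)
    assert inst.label == "none"
    assert not inst.is_positive


def test_illegal_type_pair_yields_no_instance(bbrel):
    doc = _doc_with_entities(["Geographical", "Phenotype"])
    assert enumerate_candidates(doc, bbrel) == []


def test_gold_pair_carries_its_category(bbrel):
    doc = _doc_with_entities(
        ["Microorganism", "Phenotype"],
        relations=[RelationAnnotation("R1", "Exhibits", "T1", "T2")],
    )
    (inst,) = enumerate_candidates(doc, bbrel)
    assert inst.label == "Exhibits"


def test_illegal_gold_label_kept_with_warning(bbrel, caplog):
    doc = _doc_with_entities(
        ["Microorganism", "Habitat"],
        relations=[RelationAnnotation("R1", "Exhibits", "T1", "T2")],
    )
    with caplog.at_level("WARNING"):
        (inst,) = enumerate_candidates(doc, bbrel)
    assert inst.label == "Exhibits"
    assert "violates constraints" in caplog.text


def test_type_and_distance_sequences(bbrel):
    doc = _doc_with_entities(["Microorganism", "Habitat"])
    (inst,) = enumerate_candidates(doc, bbrel)
    assert inst.entity_type_seq == ["Microorganism", "Habitat", -1]
    assert inst.dist1_seq == [0, 1, 2]
    assert inst.dist2_seq == [-1, 0, 1]


@pytest.mark.parametrize("k", [2, 3, 4, 6])
def test_pair_count_matches_brute_force(bbrel, k):
    """k mutually compatible entities give k(k-1)/2 instances; in general the
    count equals the brute-force cross product filtered by type legality."""
    rng = np.random.default_rng(k)
    types = ["Microorganism"] * k
    doc = _doc_with_entities(types)
    insts = enumerate_candidates(
        doc,
        ConstraintRule(
            name="open", categories=["none", "Rel"],
            entity_types=["Microorganism"], legal_triples=None,
        ),
    )
    assert len(insts) == k * (k - 1) // 2
    # random type mixture against the brute-force filter
    mix = [
        ["Microorganism", "Habitat", "Geographical", "Phenotype"][int(rng.integers(4))]
        for _ in range(k)
    ]
    doc2 = _doc_with_entities(mix)
    expect = sum(
        1
        for a, b in itertools.combinations(range(k), 2)
        if bbrel.pair_is_legal(mix[a], mix[b])
    )
    assert len(enumerate_candidates(doc2, bbrel)) == expect


def test_enumeration_never_pairs_across_sentences(bbrel):
    s1 = make_sentence(["Micr1", "x"], [(1, 0, "nsubj")], offset=0)
    s2 = make_sentence(["Habi1", "y"], [(1, 0, "nsubj")], offset=8)
    text = "Micr1 x Habi1 y\n"
    ents = [
        Entity("T1", "Microorganism", 0, 5, "Micr1"),
        Entity("T2", "Habitat", 8, 13, "Habi1"),
    ]
    doc = Document("d", text, entities=ents)
    attach_parses(doc, [s1, s2])
    assert enumerate_candidates(doc, bbrel) == []


def test_duplicate_span_entities_excluded(bbrel):
    doc = _doc_with_entities(["Microorganism", "Habitat"])
    dup = Entity("T9", "Habitat", doc.entities[0].char_start,
                 doc.entities[0].char_end, doc.entities[0].surface)
    doc.entities.append(dup)
    attach_parses(doc, doc.sentences)
    insts = enumerate_candidates(doc, bbrel)
    # T1-T9 share a span -> excluded; T9-T2 is a new legal pair
    pairs = {frozenset((i.e1.id, i.e2.id)) for i in insts}
    assert frozenset(("T1", "T9")) not in pairs


# -- path filtering -----------------------------------------------------------


def test_connected_tree_loses_nothing(bbrel):
    doc = _doc_with_entities(["Microorganism", "Habitat"])
    insts = enumerate_candidates(doc, bbrel)
    assert filter_no_path(insts) == insts


def test_disconnected_components_remove_instance(bbrel):
    # two-component forest: tokens {0,1} and {2} with entities either side
    sent = make_sentence(["Micr1", "x", "Habi1"], [(1, 0, "nsubj")])
    text = "Micr1 x Habi1\n"
    ents = [
        Entity("T1", "Microorganism", 0, 5, "Micr1"),
        Entity("T2", "Habitat", 8, 13, "Habi1"),
    ]
    doc = Document("d", text, entities=ents)
    attach_parses(doc, [sent])
    insts = enumerate_candidates(doc, bbrel)
    assert len(insts) == 1
    assert filter_no_path(insts) == []


def test_removal_count_matches_union_find_oracle():
    bundle = generate_corpus(SynthConfig(seed=13, n_documents=40, forest_rate=0.5))
    insts = []
    for doc in bundle.documents:
        insts.extend(enumerate_candidates(doc, bundle.task))
    kept = filter_no_path(insts)

    def uf_connected(sent, a, b):
        parent = list(range(len(sent.tokens)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h, d, _l in sent.edges:
            parent[find(h)] = find(d)
        return find(a) == find(b)

    expect = [
        i for i in insts
        if uf_connected(i.sentence, i.e1.token_span[2], i.e2.token_span[2])
    ]
    assert kept == expect
    assert len(insts) - len(kept) == len(insts) - len(expect)


# -- negative subsampling -----------------------------------------------------


def _stub(label, i=0):
    return CandidateInstance(
        doc_id=f"d{i}", sent_index=0, e1=None, e2=None, label=label, sentence=None
    )


def test_ninety_percent_deletion_uses_floor_rule():
    negs = [_stub("none", i) for i in range(17_489)]
    pos = [_stub("Lives_In", i) for i in range(1_508)]
    out = subsample_negatives(pos + negs, keep_fraction=0.10, seed=0)
    kept_neg = sum(1 for i in out if i.label == "none")
    assert len(negs) - kept_neg == 15_740
    assert sum(1 for i in out if i.label != "none") == len(pos)


def test_keep_all_is_identity():
    insts = [_stub("none", i) for i in range(10)] + [_stub("Lives_In")]
    assert subsample_negatives(insts, 1.0, seed=3) == insts


def test_subsampling_deterministic_and_seed_sensitive():
    insts = [_stub("none", i) for i in range(500)]
    a = subsample_negatives(insts, 0.4, seed=7)
    b = subsample_negatives(insts, 0.4, seed=7)
    c = subsample_negatives(insts, 0.4, seed=8)
    assert [x.doc_id for x in a] == [x.doc_id for x in b]
    assert len(a) == len(c)
    assert [x.doc_id for x in a] != [x.doc_id for x in c]


def test_bad_fraction_rejected():
    with pytest.raises(ValueError):
        subsample_negatives([], -0.1, seed=0)
    with pytest.raises(ValueError):
        subsample_negatives([], 1.5, seed=0)


# -- statistics ---------------------------------------------------------------


def test_statistics_empty():
    assert corpus_statistics([]) == {"total": 0}


def test_statistics_totals_match_category_sums():
    insts = (
        [_stub("Lives_In")] * 659
        + [_stub("Exhibits")] * 284
        + [_stub("none")] * 1053
    )
    stats = corpus_statistics(insts)
    assert stats["Lives_In"] + stats["Exhibits"] == 943
    assert stats["total"] == 1996

    big = [_stub("Rel")] * 1508 + [_stub("none")] * 17_489
    assert corpus_statistics(big)["total"] == 18_997
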