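"""Standoff reading/writing and parse attachment."""

import numpy as np
import pytest

from biorel.parses import attach_parses, read_parses, write_parses
from biorel.standoff import (
    DanglingReferenceError,
    RelationAnnotation,
    StandoffIntegrityError,
    StandoffParseError,
    read_standoff,
    write_a1,
    write_a2,
    write_predictions,
)
from biorel.synth import SynthConfig, generate_corpus

from conftest import make_sentence


TEXT = "The percentage of penicillin-resistant N. gonorrhoeae isolated here\n"


def test_empty_annotations_give_empty_document():
    doc = read_standoff("some text\n", "", "")
    assert doc.entities == [] and doc.relations == []


def test_entity_line_parses_with_type_and_surface():
    text = "The N. gonorrhoeae strain\n"
    a1 = "T1\tMicroorganism 4 18\tN. gonorrhoeae\n"
    doc = read_standoff(text, a1)
    (ent,) = doc.entities
    assert ent.etype == "Microorganism"
    assert ent.surface == "N. gonorrhoeae"
    assert (ent.char_start, ent.char_end) == (4, 18)


def test_offsets_are_zero_based_half_open_over_raw_text():
    text = "ab\ncd\n"
    doc = read_standoff(text, "T1\tHabitat 3 5\tcd\n")
    assert text[3:5] == "cd"
    assert doc.entities[0].surface == "cd"


@pytest.mark.parametrize(
    "a1,exc",
    [
        ("T1\tMicroorganism x y\tfoo\n", StandoffParseError),
        ("T1 entity line without tabs\n", StandoffParseError),
        ("T1\tMicroorganism 0 3\tWRONG\n", StandoffIntegrityError),
        ("T1\tMicroorganism 0 999\tThe\n", StandoffIntegrityError),
    ],
)
def test_malformed_or_inconsistent_a1_raises(a1, exc):
    with pytest.raises(exc):
        read_standoff(TEXT, a1)


def test_parse_error_carries_line_number():
    a1 = "T1\tMicroorganism 0 3\tThe\nT2\tbroken line\n"
    with pytest.raises(StandoffParseError, match="line 2"):
        read_standoff(TEXT, a1)


def test_relation_dialects_positional_and_role_named():
    a1 = "T1\tMicroorganism 0 3\tThe\nT2\tHabitat 4 14\tpercentage\n"
    for a2 in (
        "R1\tLives_In Arg1:T1 Arg2:T2\n",
        "R1\tLives_In Microorganism:T1 Location:T2\n",
    ):
        doc = read_standoff(TEXT, a1, a2)
        (rel,) = doc.relations
        assert (rel.rtype, rel.arg1_id, rel.arg2_id) == ("Lives_In", "T1", "T2")


def test_dangling_relation_argument_raises():
    a1 = "T1\tMicroorganism 0 3\tThe\n"
    with pytest.raises(DanglingReferenceError):
        read_standoff(TEXT, a1, "R1\tLives_In Arg1:T1 Arg2:T9\n")


def test_discontinuous_span_collapses_to_envelope(caplog):
    text = "alpha beta gamma\n"
    doc = read_standoff(text, "T1\tHabitat 0 5;11 16\talpha gamma\n")
    ent = doc.entities[0]
    assert (ent.char_start, ent.char_end) == (0, 16)


def test_roundtrip_on_synthetic_corpus():
    bundle = generate_corpus(SynthConfig(seed=11, n_documents=100))
    for doc in bundle.documents:
        back = read_standoff(
            doc.text, write_a1(doc), write_a2(doc, doc.relations, bundle.task),
            doc_id=doc.doc_id,
        )
        assert [(e.id, e.etype, e.char_start, e.char_end) for e in back.entities] == [
            (e.id, e.etype, e.char_start, e.char_end) for e in doc.entities
        ]
        assert {(r.rtype, r.pair()) for r in back.relations} == {
            (r.rtype, r.pair()) for r in doc.relations
        }


def test_write_predictions_format_and_roundtrip(bbrel):
    text = "Salm in egg products\n"
    a1 = "T1\tMicroorganism 0 4\tSalm\nT2\tHabitat 8 20\tegg products\n"
    doc = read_standoff(text, a1)
    assert write_predictions(doc, []) == ""
    out = write_predictions(
        doc, [RelationAnnotation("Rx", "Lives_In", "T1", "T2")], bbrel
    )
    assert out == "R1\tLives_In Microorganism:T1 Location:T2\n"
    back = read_standoff(text, a1, out)
    assert back.relations[0].pair() == frozenset({"T1", "T2"})


def test_write_predictions_orients_priority_type_first(bbrel):
    # entity order reversed in the annotation: habitat is T1
    text = "egg products hold Salm\n"
    a1 = "T1\tHabitat 0 12\tegg products\nT2\tMicroorganism 18 22\tSalm\n"
    doc = read_standoff(text, a1)
    out = write_predictions(
        doc, [RelationAnnotation("R9", "Lives_In", "T1", "T2")], bbrel
    )
    assert out == "R1\tLives_In Microorganism:T2 Location:T1\n"


def test_write_predictions_rejects_unknown_category_and_none(bbrel):
    text = "a b\n"
    doc = read_standoff(text, "T1\tMicroorganism 0 1\ta\nT2\tHabitat 2 3\tb\n")
    with pytest.raises(ValueError):
        write_predictions(doc, [RelationAnnotation("R1", "Made_Up", "T1", "T2")], bbrel)
    with pytest.raises(ValueError):
        write_predictions(doc, [RelationAnnotation("R1", "none", "T1", "T2")], bbrel)


# -- parse attachment ---------------------------------------------------------


def test_attach_parses_resolves_token_span():
    sent = make_sentence(["Salm", "grows", "here"], [(1, 0, "nsubj"), (1, 2, "advmod")])
    text = "Salm grows here\n"
    doc = read_standoff(text, "T1\tMicroorganism 0 4\tSalm\n")
    attach_parses(doc, [sent])
    assert doc.entities[0].token_span == (0, 0, 0)
    assert not doc.entities[0].cross_sentence


def test_attach_parses_flags_cross_sentence_entity():
    s1 = make_sentence(["one", "two"], [(0, 1, "dobj")], offset=0)
    s2 = make_sentence(["three", "four"], [(0, 1, "dobj")], offset=8)
    text = "one two three four\n"
    doc = read_standoff(text, "T1\tHabitat 4 13\ttwo three\n")
    attach_parses(doc, [s1, s2])
    assert doc.entities[0].cross_sentence
    assert doc.entities[0].token_span is None


def test_overlap_rule_covers_every_touching_token():
    # "N." and "gonorrhoeae" are separate tokens inside one entity span
    sent = make_sentence(["N.", "gonorrhoeae", "grows"], [(2, 1, "nsubj"), (1, 0, "nmod")])
    text = "N. gonorrhoeae grows\n"
    doc = read_standoff(text, "T1\tMicroorganism 0 14\tN. gonorrhoeae\n")
    attach_parses(doc, [sent])
    assert doc.entities[0].token_span == (0, 0, 1)


def test_attach_parses_rejects_shifted_offsets():
    sent = make_sentence(["Salm", "grows"], [(1, 0, "nsubj")], offset=1)  # 1-based-like
    doc = read_standoff("Salm grows\n", "T1\tMicroorganism 0 4\tSalm\n")
    with pytest.raises(StandoffIntegrityError, match="0-based"):
        attach_parses(doc, [sent])


def test_attach_parses_preserves_text_and_offsets():
    sent = make_sentence(["Salm", "grows"], [(1, 0, "nsubj")])
    doc = read_standoff("Salm grows\n", "T1\tMicroorganism 0 4\tSalm\n")
    before = (doc.text, doc.entities[0].char_start, doc.entities[0].char_end)
    attach_parses(doc, [sent])
    assert (doc.text, doc.entities[0].char_start, doc.entities[0].char_end) == before


def test_parse_sidecar_roundtrip():
    bundle = generate_corpus(SynthConfig(seed=5, n_documents=10))
    text = write_parses(bundle.parses)
    back = read_parses(text)
    assert set(back) == set(bundle.parses)
    for doc_id, sents in bundle.parses.items():
        got = back[doc_id]
        assert len(got) == len(sents)
        for a, b in zip(got, sents):
            assert [t.word for t in a.tokens] == [t.word for t in b.tokens]
            assert sorted(a.edges) == sorted(b.edges)
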