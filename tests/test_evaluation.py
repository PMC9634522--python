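"""Micro-averaged scoring, cluster pooling, and the F1 identity."""

import numpy as np
import pytest

from biorel.evaluation import (
    cluster_report,
    f_score,
    make_key,
    round_half_up,
    score,
)


def _keys(spec):
    """spec: iterable of (doc, pair-tuple, category)."""
    return {make_key(d, a, b, c) for d, (a, b), c in spec}


def test_perfect_prediction_scores_100():
    g = _keys([("d1", ("T1", "T2"), "Lives_In"), ("d2", ("T1", "T3"), "Exhibits")])
    r = score(g, g)
    assert (r.aggregate.precision, r.aggregate.recall, r.aggregate.f1) == (1, 1, 1)


@pytest.mark.parametrize(
    "p,r,f1",
    [
        (69.50, 62.05, 65.56),   # overall: harmonic mean of the printed P/R
        (70.18, 86.96, 77.67),   # intra-sentence subset of the second category
        (69.38, 56.64, 62.36),
        (69.75, 68.27, 69.00),
        (69.77, 77.92, 73.62),
    ],
)
def test_f1_identity_reproduces_printed_cells(p, r, f1):
    # the published P/R are themselves rounded to 2 dp, so the recomputed
    # harmonic mean can differ from the printed F1 by one unit in the last
    # place; agreement is asserted at printed precision
    assert abs(round_half_up(f_score(p, r)) - f1) <= 0.01


def test_f_score_zero_denominator():
    assert f_score(0.0, 0.0) == 0.0


def test_rounding_is_half_up():
    assert round_half_up(65.565) == 65.57
    assert round_half_up(65.564) == 65.56


def test_counts_match_set_intersection_oracle():
    rng = np.random.default_rng(0)
    docs = [f"d{i}" for i in range(5)]
    cats = ["A", "B", "C"]

    def random_set(n):
        out = set()
        for _ in range(n):
            d = docs[rng.integers(5)]
            pair = tuple(sorted(rng.choice(10, size=2, replace=False)))
            out.add(make_key(d, f"T{pair[0]}", f"T{pair[1]}", cats[rng.integers(3)]))
        return out

    for _ in range(20):
        pred, gold = random_set(15), random_set(15)
        r = score(pred, gold)
        assert r.aggregate.tp == len(pred & gold)
        assert r.aggregate.fp == len(pred - gold)
        assert r.aggregate.fn == len(gold - pred)


def test_aggregate_equals_sum_of_per_category_counts():
    pred = _keys([("d", ("a", "b"), "A"), ("d", ("a", "c"), "B"), ("d", ("b", "c"), "B")])
    gold = _keys([("d", ("a", "b"), "A"), ("d", ("a", "c"), "A"), ("d", ("x", "y"), "B")])
    r = score(pred, gold)
    for field in ("tp", "fp", "fn"):
        assert getattr(r.aggregate, field) == sum(
            getattr(c, field) for c in r.per_category.values()
        )


def test_swapping_predicted_and_gold_swaps_precision_recall():
    rng = np.random.default_rng(4)
    pred = _keys([("d", (f"a{i}", f"b{i}"), "A") for i in rng.choice(30, 12, replace=False)])
    gold = _keys([("d", (f"a{i}", f"b{i}"), "A") for i in rng.choice(30, 9, replace=False)])
    r1 = score(pred, gold)
    r2 = score(gold, pred)
    assert r1.aggregate.precision == pytest.approx(r2.aggregate.recall)
    assert r1.aggregate.recall == pytest.approx(r2.aggregate.precision)
    assert r1.aggregate.f1 == pytest.approx(r2.aggregate.f1)


def test_unordered_pair_semantics():
    pred = {make_key("d", "T2", "T1", "A")}
    gold = {make_key("d", "T1", "T2", "A")}
    assert score(pred, gold).aggregate.f1 == 1.0


def test_none_prediction_rejected():
    with pytest.raises(ValueError):
        score({make_key("d", "a", "b", "none")}, set())


def test_duplicates_collapse_with_warning(caplog):
    keys = [make_key("d", "a", "b", "A"), make_key("d", "b", "a", "A")]
    with caplog.at_level("WARNING"):
        r = score(keys, keys)
    assert r.aggregate.tp == 1


def test_intersentence_gold_counts_as_recall_miss():
    gold = _keys([("d", ("a", "b"), "A"), ("d", ("c", "e"), "A")])
    intra = {make_key("d", "a", "b", "A")}
    pred = {make_key("d", "a", "b", "A")}
    r = score(pred, gold, intrasentence_gold=intra)
    assert r.aggregate.recall == pytest.approx(0.5)
    assert r.intrasentence.aggregate.recall == pytest.approx(1.0)
    assert r.intrasentence.aggregate.f1 > r.aggregate.f1


# -- clusters -----------------------------------------------------------------


def test_single_cluster_equals_aggregate():
    pred = _keys([("d", ("a", "b"), "A"), ("d", ("a", "c"), "B")])
    gold = _keys([("d", ("a", "b"), "A"), ("d", ("x", "y"), "B")])
    r = score(pred, gold)
    cl = cluster_report(r, {"A": "all", "B": "all"})
    assert cl["all"].tp == r.aggregate.tp
    assert cl["all"].f1 == pytest.approx(r.aggregate.f1)


def test_cluster_tp_conservation():
    pred = _keys([("d", ("a", "b"), "A"), ("d", ("a", "c"), "B"), ("d", ("b", "c"), "C")])
    gold = _keys([("d", ("a", "b"), "A"), ("d", ("a", "c"), "B"), ("d", ("p", "q"), "C")])
    r = score(pred, gold)
    cl = cluster_report(r, {"A": "x", "B": "x", "C": "y"})
    assert sum(c.tp for c in cl.values()) == r.aggregate.tp


def test_three_category_cluster_hand_computation():
    pred = _keys(
        [("d", ("1", "2"), "A"), ("d", ("3", "4"), "B"), ("d", ("5", "6"), "C"),
         ("d", ("7", "8"), "C")]
    )
    gold = _keys(
        [("d", ("1", "2"), "A"), ("d", ("3", "4"), "A"), ("d", ("5", "6"), "C")]
    )
    r = score(pred, gold)
    cl = cluster_report(r, {"A": "reg", "B": "reg", "C": "int"})
    # reg: tp=1 (A hit), fp=1 (B), fn=1 (missed A) -> P=0.5 R=0.5 F1=0.5
    assert (cl["reg"].tp, cl["reg"].fp, cl["reg"].fn) == (1, 1, 1)
    assert cl["reg"].f1 == pytest.approx(0.5)
    # int: tp=1, fp=1, fn=0 -> P=0.5, R=1, F1=2/3
    assert cl["int"].f1 == pytest.approx(2 / 3)


def test_unmapped_category_raises():
    r = score(_keys([("d", ("a", "b"), "A")]), _keys([("d", ("a", "b"), "Z")]))
    with pytest.raises(ValueError, match="Z"):
        cluster_report(r, {"A": "x"})
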