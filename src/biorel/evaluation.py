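"""Micro-averaged relation-extraction scoring.

A predicted relation is correct iff its (document, unordered entity
pair, category) key matches a gold relation exactly.  Precision, recall
and F1 are computed from TP/FP/FN pooled over all categories
(micro-averaging), per category, for the intra-sentence gold subset,
and optionally pooled per user-supplied category cluster.  Gold
relations whose entities lie in different sentences still count as
recall misses for an intra-sentence system — which is why published
intra-sentence F1s exceed the overall ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

log = logging.getLogger(__name__)

# A relation key: (doc_id, frozenset({entity ids}), category)
RelationKey = tuple


def make_key(doc_id: str, e1_id: str, e2_id: str, category: str) -> RelationKey:
    return (doc_id, frozenset((e1_id, e2_id)), category)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def round_half_up(x: float, places: int = 2) -> float:
    """Display rounding used by the printed tables (2.675 -> 2.68)."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f_score(self.precision, self.recall)

    def as_percent_row(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": round_half_up(100.0 * self.precision),
            "recall": round_half_up(100.0 * self.recall),
            "f1": round_half_up(100.0 * self.f1),
        }


@dataclass
class EvalReport:
    aggregate: CategoryCounts
    per_category: dict[str, CategoryCounts]
    intrasentence: Optional["EvalReport"] = None
    clusters: Optional[dict[str, CategoryCounts]] = None

    def as_dict(self) -> dict:
        d = {
            "aggregate": self.aggregate.as_percent_row(),
            "per_category": {
                k: v.as_percent_row() for k, v in sorted(self.per_category.items())
            },
        }
        if self.intrasentence is not None:
            d["intrasentence"] = self.intrasentence.as_dict()
        if self.clusters is not None:
            d["clusters"] = {k: v.as_percent_row() for k, v in self.clusters.items()}
        return d


def _dedupe(keys: Iterable[RelationKey], what: str) -> set:
    keys = list(keys)
    uniq = set(keys)
    if len(uniq) < len(keys):
        log.warning("%s: %d duplicate keys collapsed", what, len(keys) - len(uniq))
    return uniq


def score(
    predicted: Iterable[RelationKey],
    gold: Iterable[RelationKey],
    intrasentence_gold: Optional[set] = None,
) -> EvalReport:
    """Score a predicted relation set against the gold set.

    ``none`` predictions must already be excluded.  When
    ``intrasentence_gold`` (the subset of gold keys whose entities share
    a sentence) is given, a sub-report restricted to those gold keys —
    with predictions restricted to the same (doc, pair) universe — is
    attached.
    """
    pred = _dedupe(predicted, "predicted")
    gold_set = _dedupe(gold, "gold")
    if any(k[2] == "none" for k in pred):
        raise ValueError("'none' must not appear in the predicted relation set")

    cats = sorted({k[2] for k in gold_set} | {k[2] for k in pred})
    per = {c: CategoryCounts() for c in cats}
    for k in pred:
        if k in gold_set:
            per[k[2]].tp += 1
        else:
            per[k[2]].fp += 1
    for k in gold_set:
        if k not in pred:
            per[k[2]].fn += 1
    agg = CategoryCounts(
        tp=sum(c.tp for c in per.values()),
        fp=sum(c.fp for c in per.values()),
        fn=sum(c.fn for c in per.values()),
    )
    report = EvalReport(aggregate=agg, per_category=per)
    if intrasentence_gold is not None:
        intra_gold = gold_set & set(intrasentence_gold)
        intra_pairs = {(k[0], k[1]) for k in intra_gold}
        intra_pred = {k for k in pred if (k[0], k[1]) in intra_pairs or k in intra_gold}
        report.intrasentence = score(intra_pred, intra_gold)
    return report


def cluster_report(
    report: EvalReport, mapping: Mapping[str, str]
) -> dict[str, CategoryCounts]:
    """Pool per-category counts into clusters, then score each cluster."""
    missing = [c for c in report.per_category if c not in mapping]
    if missing:
        raise ValueError(f"cluster mapping misses categories: {missing}")
    out: dict[str, CategoryCounts] = {}
    for cat, counts in report.per_category.items():
        cl = out.setdefault(mapping[cat], CategoryCounts())
        cl.tp += counts.tp
        cl.fp += counts.fp
        cl.fn += counts.fn
    report.clusters = out
    return out
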