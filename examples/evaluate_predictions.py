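"""Score a predicted relation set against gold with the micro metrics.

Builds tiny predicted/gold sets keyed by (document, unordered entity
pair, category) and prints the per-category and aggregate table.
"""

from biorel.evaluation import cluster_report, make_key, score

gold = {
    make_key("doc1", "T1", "T2", "Lives_In"),
    make_key("doc1", "T1", "T3", "Exhibits"),
    make_key("doc2", "T1", "T2", "Lives_In"),
}
predicted = {
    make_key("doc1", "T2", "T1", "Lives_In"),   # argument order is irrelevant
    make_key("doc1", "T1", "T3", "Lives_In"),   # wrong category -> FP + FN
}

report = score(predicted, gold)
for cat, c in sorted(report.per_category.items()):
    row = c.as_percent_row()
    print(f"{cat:10s} TP={row['tp']} FP={row['fp']} FN={row['fn']} "
          f"P={row['precision']:.2f} R={row['recall']:.2f} F1={row['f1']:.2f}")
agg = report.aggregate.as_percent_row()
print(f"{'micro':10s} TP={agg['tp']} FP={agg['fp']} FN={agg['fn']} "
      f"P={agg['precision']:.2f} R={agg['recall']:.2f} F1={agg['f1']:.2f}")

clusters = cluster_report(report, {"Lives_In": "location", "Exhibits": "property"})
for name, c in clusters.items():
    print(f"cluster {name}: F1={100 * c.f1:.2f}")

# Micro scores pool TP/FP/FN over categories before computing P/R/F1,
# so frequent categories weigh more; a category-mismatched prediction
# costs both a false positive and a false negative.
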