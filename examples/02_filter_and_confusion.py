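"""Filter cells, then compare two annotations with a Jaccard confusion matrix.

A planted two-taxonomy table stands in for, e.g., a study's own clusters
versus labels transferred from a reference atlas. We restrict to two
reference types and dot-plot the correspondence.
"""

import numpy as np

import annotlink as al

spec = al.MixingSpec(
    ref_labels=["Sst_1", "Sst_25", "Pvalb_1", "Micro_1"],
    study_labels=["IN-SST", "IN-PV", "MG"],
    counts=[400, 300, 300, 200],
    matrix=np.array(
        [
            [0.95, 0.05, 0.00],
            [0.90, 0.10, 0.00],
            [0.10, 0.90, 0.00],
            [0.00, 0.00, 1.00],
        ]
    ),
    seed=11,
)
t = al.make_taxonomy_pair(spec)

fs = al.FilterSet([al.CategoricalFilter("ref_label", frozenset({"Sst_1", "Sst_25"}))])
print(al.selection_summary(t, fs))  # retained/total before materializing
sub = al.apply_filter_set(t, fs)

cm = al.crosstab(sub, "ref_label", "study_label")
print("\nCounts:")
print(cm.to_frame())
print("\nJaccard similarity (intersection over union of the record sets):")
print(cm.to_frame(al.jaccard_view(cm)).round(3))
# Both Sst types map overwhelmingly to IN-SST, so their Jaccard values split
# roughly by relative size; row fractions show per-type mapping rates:
print("\nRow fractions (each row sums to 1):")
print(cm.to_frame(al.fraction_view(cm, "row")).round(3))

al.render_confusion(
    cm, al.PlotStyle(metric="jaccard"), "confusion.png", data_path="confusion.csv"
)
print("\nWrote confusion.png and its plot-data sidecar confusion.csv.")
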