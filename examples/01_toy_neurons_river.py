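"""The shifting-size-classification toy example.

Eight pyramidal neurons are first classified into two size groups; adding a
ninth neuron triggers a reclassification into three groups. The crosstab and
river model show how the category definitions shifted.
"""

import annotlink as al

t = al.make_toy_neurons()
print(t)

cm = al.crosstab(t, "size_v1", "size_v2")
print("\nCrosstab of the two size annotations (counts):")
print(cm.to_frame())
print(f"\nRecords shared between the annotations: {cm.total}")
# 8 — the ninth neuron has no first-pass label, so it drops out of the
# pairwise comparison.

model = al.river_model(t, ["size_v1", "size_v2"])
print(f"First-column nodes:  {model.nodes['size_v1']}")
print(f"Second-column nodes: {model.nodes['size_v2']}")
# Two groups became three: the old 'large' group split into medium + large,
# and each link count below is the number of neurons flowing between them.
for link in model.links:
    print(f"  {link.source:>6} -> {link.target:<7} {link.count} neurons")

al.render_river(model, al.PlotStyle(), "toy_river.png", data_path="toy_river.json")
print("\nWrote toy_river.png (ribbon widths proportional to the link counts).")
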