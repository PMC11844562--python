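"""Probabilistically express one study's labels on reference cells.

From cells carrying both a reference label and a study label, the
conditional proportions p(study label | reference label) are estimated;
reference cells are then assigned study labels by independent draws from
those distributions. A reference type the study never saw gets the reserved
'noMappedCells' label.
"""

import pandas as pd

import annotlink as al

# shared cells: a glia-focused study saw microglia and astrocytes only

pairing = al.CellTable(
    [f"s{i}" for i in range(8)],
    pd.DataFrame(
        {
            "supertype": ["Micro_1"] * 4 + ["Astro_2"] * 2 + ["Sst_25"] * 2,
            "study_type": ["MG1", "MG1", "MG2", "MG1", "AST1", "AST1", None, None],
        }
    ),
    {"supertype": al.CATEGORICAL, "study_type": al.CATEGORICAL},
)

pt = al.proportion_table(pairing, "supertype", "study_type")
print("Proportion table (long format):")
print(pt.to_frame())
# Micro_1 splits 3/4 MG1, 1/4 MG2; Sst_25 was never co-observed with a
# study label, so it carries noMappedCells with probability 1.

ref = al.CellTable(
    [f"c{i}" for i in range(9)],
    pd.DataFrame({"supertype": ["Micro_1"] * 4 + ["Astro_2"] * 2 + ["Sst_25"] * 3}),
    {"supertype": al.CATEGORICAL},
)
out = al.probabilistic_assign(ref, pt, "supertype", "study_type", seed=42)
print("\nAssigned labels on the reference cells:")
print(out.to_frame().to_string(index=False))

# broad labels inferred from the fine ones
h = al.LabelHierarchy({"MG1": "Microglia", "MG2": "Microglia", "AST1": "Astrocyte"})
broad = al.infer_broad_labels(out, "study_type", h, "study_class")
print("\nBroad classes:", list(broad.column("study_class")))
# Every neuronal cell stays noMappedCells at both resolutions — the study
# simply has no vocabulary for it.
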