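"""Cap table size by even-by-cluster subsampling.

Uniform subsampling would nearly erase rare cell types; waterfilled quotas
keep small clusters whole and split the remaining budget evenly among the
large ones.
"""

import pandas as pd

import annotlink as al

sizes = {"Endo": 50, "Sst_25": 400, "Oligo_1": 30_000, "L23_IT": 60_000}
labels = [k for k, n in sizes.items() for _ in range(n)]
t = al.CellTable(
    [f"c{i}" for i in range(len(labels))],
    pd.DataFrame({"supertype": labels}),
    {"supertype": al.CATEGORICAL},
)

sub, plan = al.even_subsample(t, "supertype", cap=10_000, seed=7)
print(plan.to_frame().to_string(index=False))
print(f"\nRetained {sub.n_cells} of {t.n_cells} cells (cap 10,000).")
# Endo and Sst_25 are kept whole; the two large clusters split the rest of
# the budget evenly, so downstream fractions stay usable for rare types.
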