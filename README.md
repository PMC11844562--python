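# annotlink

Compare, harmonize and visualize cell-level annotations across single-cell
studies — headless, from Python or the shell.

Single-cell and single-nucleus RNA-seq studies each define their own cell
type classifications ("taxonomies"), with inconsistent names and very
different resolutions: one study's 16 microglial populations are another's
three. Linking cell types — and the knowledge attached to them, such as
reported abundance changes in Alzheimer's disease — across studies therefore
requires comparing categorical annotations defined on a shared set of cells.
`annotlink` implements that comparison workflow for anyone who has such a
table: atlas builders publishing taxonomy crosswalks, disease researchers
checking whether a cell type's abundance change replicates across cohorts,
and users of label-transfer tools (MapMyCells, Azimuth and the like)
comparing transferred labels with their own clusters.

## What it computes

The input is a **cell table** (rows = cells, columns = categorical or
numeric annotations; csv, csv.gz, feather, or the `obs` metadata of an
h5ad) plus an optional **annotation-info table** giving each (column, value)
pair a display order, a description, and a direction of abundance change
with disease (up / down / unchanged / unknown). On top of these:

- **Filtering** — per-column categorical include/invert rules and inclusive
  numeric ranges, composed conjunctively.
- **Confusion matrices** — for two categorical columns A, B on the same
  cells, the counts n<sub>ij</sub> = |{cells: A=i, B=j}| over cells
  non-missing in both, viewable as raw counts, row/column fractions
  (n<sub>ij</sub>/n<sub>i·</sub>, rows sum to 1), or Jaccard similarity
  J<sub>ij</sub> = n<sub>ij</sub> / (n<sub>i·</sub> + n<sub>·j</sub> −
  n<sub>ij</sub>) = |A<sub>i</sub> ∩ B<sub>j</sub>| / |A<sub>i</sub> ∪
  B<sub>j</sub>|.
- **River (alluvial) models** — two or more annotation columns as ordered
  node columns, with links between adjacent columns carrying shared-cell
  counts (the pairwise crosstab), plus value breakdowns of a single focal
  category and tallies of the disease-direction tags of its matches.
- **Probabilistic harmonization** — from cells carrying both a reference
  label s and a study label c, estimate p(c | s) = n<sub>sc</sub> /
  n<sub>s</sub>; assign each reference cell an independent draw from its
  label's distribution; reference labels a study never observed get the
  reserved label `noMappedCells`; broad labels are inferred from fine ones
  through an explicit hierarchy.
- **Even-by-cluster subsampling** — cap a table (default 500,000 records)
  with waterfilled per-cluster quotas: small clusters are kept whole, large
  ones split the remaining budget evenly, so rare cell types survive.
- **Plots** — river, confusion dot plot, bee swarm and scatter renderers
  (png/svg/pdf) that can also emit their plot-ready numbers as CSV/JSON
  sidecars.

## Worked example

Eight pyramidal neurons are classified into two groups by size; a ninth,
intermediate-sized neuron arrives and the classification is redone into
three groups. How did the categories shift?

```python
import annotlink as al

t = al.make_toy_neurons()
cm = al.crosstab(t, "size_v1", "size_v2")
print(cm.to_frame()); print("shared:", cm.total)

model = al.river_model(t, ["size_v1", "size_v2"])
for link in model.links:
    print(f"{link.source:>6} -> {link.target:<7} {link.count} neurons")
```

prints

```
       small  large  medium
large      0      2      2
small      4      0      0
shared: 8
 large -> large   2 neurons
 large -> medium  2 neurons
 small -> small   4 neurons
```

Eight cells are shared between the annotations (the ninth neuron has no
first-pass label, so it drops out of the pairwise comparison). The old
"small" group survived intact; the old "large" group split in two — the
river plot (`al.render_river(model, al.PlotStyle(), "river.png")`) draws
exactly these three links, with ribbon widths proportional to the counts.

The same operations are available from the shell:

```sh
annotlink fixtures toy-neurons --out toy.csv
annotlink compare --in toy.csv --a size_v1 --b size_v2 --metric jaccard --out cm.csv
annotlink river   --in toy.csv --cols size_v1,size_v2 --out river.json
```

See `examples/` for narrative scripts covering filtering + confusion
matrices, cross-study harmonization, and subsampling.

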