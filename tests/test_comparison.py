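import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import annotlink as al
from annotlink.io import CATEGORICAL, NUMERIC, AnnotationInfo, ValidationError
from annotlink.io import InfoEntry
from conftest import make_table, random_table
from oracles import (
    brute_crosstab,
    brute_jaccard,
    brute_node_count,
    brute_row_fraction,
)


class TestCrosstab:
    def test_self_crosstab_is_diagonal(self):
        t = make_table(
            {"g": ["a"] * 3 + ["b"] * 5}, {"g": CATEGORICAL}
        )
        cm = al.crosstab(t, "g", "g")
        df = cm.to_frame()
        assert df.loc["b", "b"] == 5 and df.loc["a", "a"] == 3
        assert cm.total == 8
        assert (cm.counts - np.diag(np.diag(cm.counts)) == 0).all()

    def test_toy_neurons_share_eight_cells(self):
        """The 8/9-neuron example: eight records complete in both size
        annotations, so the crosstab totals 8."""
        t = al.make_toy_neurons()
        cm = al.crosstab(t, "size_v1", "size_v2")
        assert cm.total == 8

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        cm = al.crosstab(t, "anno_a", "anno_b")
        expected = brute_crosstab(t, "anno_a", "anno_b")
        df = cm.to_frame()
        for (va, vb), n in expected.items():
            assert df.loc[va, vb] == n
        assert cm.total == sum(expected.values())

    def test_numeric_column_rejected(self, simple_table):
        with pytest.raises(ValidationError):
            al.crosstab(simple_table, "cls", "n_genes")

    def test_total_invariant_under_row_permutation(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n_max=200)
        perm = rng.permutation(t.n_cells)
        cm1 = al.crosstab(t, "anno_a", "anno_b")
        cm2 = al.crosstab(t.take(perm), "anno_a", "anno_b")
        assert cm1.total == cm2.total
        assert cm1.to_frame().sort_index(axis=0).sort_index(axis=1).equals(
            cm2.to_frame().sort_index(axis=0).sort_index(axis=1)
        )

    def test_info_order_controls_labels(self, simple_table, simple_info):
        cm = al.crosstab(simple_table, "cls", "cls", info=simple_info)
        assert cm.row_labels == ["Sst", "Endo", "Micro"]

    def test_fallback_order_count_then_lexicographic(self):
        t = make_table(
            {"g": ["b"] * 2 + ["a"] * 2 + ["z"] * 5}, {"g": CATEGORICAL}
        )
        cm = al.crosstab(t, "g", "g")
        assert cm.row_labels == ["z", "a", "b"]


class TestJaccardView:
    def test_self_crosstab_identity_pattern(self):
        t = make_table({"g": ["a", "a", "b"]}, {"g": CATEGORICAL})
        j = al.jaccard_view(al.crosstab(t, "g", "g"))
        assert np.allclose(j, np.eye(2))

    def test_nested_sets(self):
        """A 3-record category fully inside a 9-record category: J = 3/9."""
        t = make_table(
            {
                "a": ["x"] * 3 + ["y"] * 6,
                "b": ["big"] * 9,
            },
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        cm = al.crosstab(t, "a", "b")
        j = al.jaccard_view(cm)
        i, k = cm.row_labels.index("x"), cm.col_labels.index("big")
        assert j[i, k] == pytest.approx(3 / 9)
        assert j[i, k] == pytest.approx(brute_jaccard(t, "a", "b", "x", "big"))

    def test_disjoint_values_zero(self):
        """Record sets that never co-occur have J = 0; the co-occurring
        pairs here are identical singletons with J = 1."""
        t = make_table(
            {"a": ["x", "y"], "b": ["p", "q"]},
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        cm = al.crosstab(t, "a", "b")
        j = al.jaccard_view(cm)
        for i, va in enumerate(cm.row_labels):
            for k, vb in enumerate(cm.col_labels):
                expected = brute_jaccard(t, "a", "b", va, vb)
                assert j[i, k] == expected
        assert sorted(j.flat) == [0.0, 0.0, 1.0, 1.0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_under_transpose(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_max=200)
        cm = al.crosstab(t, "anno_a", "anno_b")
        j_ab = al.jaccard_view(cm)
        j_ba = al.jaccard_view(al.crosstab(t, "anno_b", "anno_a"))
        # align label orders before comparing
        import pandas as pd

        df_ab = pd.DataFrame(j_ab, index=cm.row_labels, columns=cm.col_labels)
        cm_ba = al.crosstab(t, "anno_b", "anno_a")
        df_ba = pd.DataFrame(j_ba, index=cm_ba.row_labels, columns=cm_ba.col_labels).T
        df_ba = df_ba.reindex(index=df_ab.index, columns=df_ab.columns)
        assert np.allclose(df_ab.to_numpy(), df_ba.to_numpy())


class TestFractionView:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        cm = al.crosstab(t, "anno_a", "anno_b")
        fr = al.fraction_view(cm, "row")
        sums = fr.sum(axis=1)
        nonempty = cm.row_totals() > 0
        assert np.all(np.abs(sums[nonempty] - 1.0) <= 1e-12)
        assert np.all(sums[~nonempty] == 0)
        fc = al.fraction_view(cm, "column")
        csums = fc.sum(axis=0)
        assert np.all(np.abs(csums[cm.col_totals() > 0] - 1.0) <= 1e-12)

    def test_single_column_cm_rows_are_one(self):
        t = make_table(
            {"a": ["x", "y", "x"], "b": ["only"] * 3},
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        fr = al.fraction_view(al.crosstab(t, "a", "b"), "row")
        assert np.all(fr == 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, n_max=300)
        cm = al.crosstab(t, "anno_a", "anno_b")
        fr = al.fraction_view(cm, "row")
        for i, va in enumerate(cm.row_labels):
            for j, vb in enumerate(cm.col_labels):
                assert fr[i, j] == pytest.approx(
                    brute_row_fraction(t, "anno_a", "anno_b", va, vb)
                )

    def test_bad_axis(self, simple_table):
        cm = al.crosstab(simple_table, "cls", "cls")
        with pytest.raises(ValueError):
            al.fraction_view(cm, "diagonal")


class TestRiverModel:
    def test_identical_columns_one_link_per_category(self):
        t = make_table(
            {"a": ["x", "x", "y", "z"], "b": ["x", "x", "y", "z"]},
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        model = al.river_model(t, ["a", "b"])
        links = model.links_between("a", "b")
        assert len(links) == 3
        assert {(l.source, l.target, l.count) for l in links} == {
            ("x", "x", 2), ("y", "y", 1), ("z", "z", 1)
        }

    def test_toy_neurons_three_nodes_in_second_column(self):
        """Adding the ninth neuron reclassifies into three size groups."""
        model = al.river_model(al.make_toy_neurons(), ["size_v1", "size_v2"])
        assert len(model.nodes["size_v2"]) == 3
        assert len(model.nodes["size_v1"]) == 2

    def test_fewer_than_two_columns_error(self, simple_table):
        with pytest.raises(ValidationError):
            al.river_model(simple_table, ["cls"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_link_set_equals_crosstab_nonzero_cells(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_max=200)
        model = al.river_model(t, ["anno_a", "anno_b"])
        cm = al.crosstab(t, "anno_a", "anno_b")
        link_set = {
            (l.source, l.target): l.count
            for l in model.links_between("anno_a", "anno_b")
        }
        expected = {
            (cm.row_labels[i], cm.col_labels[j]): int(cm.counts[i, j])
            for i, j in zip(*np.nonzero(cm.counts))
        }
        assert link_set == expected

    def test_three_column_chain_conserves_counts(self):
        """Per node, link totals equal the node count restricted to records
        complete in the adjacent column pair."""
        rng = np.random.default_rng(5)
        n = 300
        cols = {}
        for name in ("s1", "s2", "s3"):
            vals = [f"{name}_v{j}" for j in rng.integers(0, 4, size=n)]
            cols[name] = [v if rng.random() > 0.15 else None for v in vals]
        t = make_table(cols, {c: CATEGORICAL for c in cols})
        model = al.river_model(t, ["s1", "s2", "s3"])
        for ca, cb in (("s1", "s2"), ("s2", "s3")):
            links = model.links_between(ca, cb)
            cm = al.crosstab(t, ca, cb)
            for i, src in enumerate(cm.row_labels):
                outgoing = sum(l.count for l in links if l.source == src)
                assert outgoing == cm.row_totals()[i]
            for j, tgt in enumerate(cm.col_labels):
                incoming = sum(l.count for l in links if l.target == tgt)
                assert incoming == cm.col_totals()[j]

    def test_node_counts_are_per_column_nonmissing(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, n_max=150)
        model = al.river_model(t, ["anno_a", "anno_b"])
        for col in ("anno_a", "anno_b"):
            for value, count in model.nodes[col]:
                assert count == brute_node_count(t, col, value)

    def test_json_document_schema(self):
        model = al.river_model(al.make_toy_neurons(), ["size_v1", "size_v2"])
        doc = model.to_dict()
        assert set(doc) == {"columns", "nodes", "links"}
        assert doc["columns"] == ["size_v1", "size_v2"]
        assert all(
            set(l) == {"source_column", "target_column", "source", "target", "count"}
            for l in doc["links"]
        )


class TestValueBreakdown:
    def test_all_records_to_single_value(self):
        t = make_table(
            {"a": ["focal"] * 10 + ["other"] * 5, "b": ["tgt"] * 10 + ["x"] * 5},
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        bd = al.value_breakdown(t, "a", "focal", ["b"])
        assert len(bd.per_column["b"]) == 1
        assert bd.per_column["b"][0].value == "tgt"
        assert bd.per_column["b"][0].count == 10

    def test_counts_equal_filtered_crosstab_row(self):
        rng = np.random.default_rng(23)
        t = random_table(rng, n_max=400)
        cm = al.crosstab(t, "anno_a", "anno_b")
        focal = cm.row_labels[0]
        bd = al.value_breakdown(t, "anno_a", focal, ["anno_b"])
        got = {e.value: e.count for e in bd.per_column["anno_b"]}
        i = cm.row_labels.index(focal)
        expected = {
            cm.col_labels[j]: int(cm.counts[i, j])
            for j in range(len(cm.col_labels))
            if cm.counts[i, j] > 0
        }
        assert got == expected

    def test_absent_focal_value_warns_and_is_empty(self, simple_table):
        with pytest.warns(UserWarning, match="Astro"):
            bd = al.value_breakdown(simple_table, "cls", "Astro", ["cls"])
        assert bd.is_empty

    def test_direction_tags_come_from_info(self, simple_table, simple_info):
        bd = al.value_breakdown(
            simple_table, "cls", "Sst", ["cls"], info=simple_info
        )
        assert bd.per_column["cls"][0].direction == "down"

    def test_absent_column_error(self, simple_table):
        with pytest.raises(KeyError):
            al.value_breakdown(simple_table, "cls", "Endo", ["ghost"])


def _planted_studies_table_and_info():
    """Nine synthetic 'studies'; the focal reference type maps to values
    tagged 'down' in exactly six of them, mirroring the reported pattern of
    consistent interneuron loss."""
    n = 60
    ref = ["Sst_25"] * n
    columns = {"ref": ref}
    entries = []
    down_studies = 6
    for i in range(9):
        col = f"study_{i}"
        columns[col] = [f"S{i}_typeA"] * n
        direction = "down" if i < down_studies else "unchanged"
        entries.append(InfoEntry(col, f"S{i}_typeA", order=0, direction=direction))
    t = make_table(columns, {c: CATEGORICAL for c in columns})
    return t, AnnotationInfo(entries)


class TestDirectionConcordance:
    def test_down_dominant_in_six_of_nine_studies(self):
        t, info = _planted_studies_table_and_info()
        bd = al.value_breakdown(
            t, "ref", "Sst_25", [f"study_{i}" for i in range(9)], info=info
        )
        tally = al.direction_concordance(bd, info)
        assert tally.n_dominant("down") == 6
        assert tally.n_dominant("unchanged") == 3

    def test_all_unknown_dominant_unknown(self):
        t, _ = _planted_studies_table_and_info()
        bd = al.value_breakdown(
            t, "ref", "Sst_25", [f"study_{i}" for i in range(9)]
        )
        tally = al.direction_concordance(bd)
        assert tally.n_dominant("unknown") == 9

    def test_single_up_value(self):
        t = make_table(
            {"a": ["f"] * 4, "b": ["v"] * 4},
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        info = AnnotationInfo([InfoEntry("b", "v", order=0, direction="up")])
        bd = al.value_breakdown(t, "a", "f", ["b"], info=info)
        tally = al.direction_concordance(bd, info)
        assert tally.dominant["b"] == "up"
        assert tally.per_column["b"] == {"up": 1}

    def test_by_cell_weighting_and_tie_to_unknown(self):
        t = make_table(
            {
                "a": ["f"] * 6,
                "b": ["u1", "u1", "u1", "u1", "d1", "d1"],
            },
            {"a": CATEGORICAL, "b": CATEGORICAL},
        )
        info = AnnotationInfo(
            [
                InfoEntry("b", "u1", order=0, direction="up"),
                InfoEntry("b", "d1", order=1, direction="down"),
            ]
        )
        bd = al.value_breakdown(t, "a", "f", ["b"], info=info)
        by_value = al.direction_concordance(bd, info, weighting="by_value")
        assert by_value.dominant["b"] == "unknown"  # 1 vs 1 tie
        by_cell = al.direction_concordance(bd, info, weighting="by_cell")
        assert by_cell.dominant["b"] == "up"  # 4 cells vs 2
        assert by_cell.per_column["b"] == {"up": 4, "down": 2}
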