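import numpy as np
import pandas as pd
import pytest

import tidymat as tm
from tidymat.core_model import Context
from tidymat.testing import assert_containers_equal


class TestMutate:
    def test_new_assay_log1p(self):
        obj = tm.make_annotated_matrix(assays={"counts": [[0, 1], [2, 3]]})
        out = tm.mutate(obj, "logcounts = log1p(counts)")
        np.testing.assert_allclose(
            out.assays["logcounts"], np.log([[1, 2], [3, 4]])
        )
        np.testing.assert_array_equal(out.assays["counts"], [[0, 1], [2, 3]])

    def test_cols_sentinel_logical(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1, 2]]}, col_data={"lib_size": [5, 15]}
        )
        out = tm.mutate(obj, "cols(filtered = lib_size > 10)")
        np.testing.assert_array_equal(out.col_data["filtered"], [False, True])

    def test_grouped_centering_matches_oracle(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1.0, 2.0, 10.0], [3.0, 4.0, 20.0]]},
            col_data={"grp": ["a", "a", "b"]},
        )
        g = tm.group_by(obj, "cols(grp)")
        out = tm.mutate(g, "centered = counts - mean(counts)")
        # block means: group a -> 2.5 over 4 cells, group b -> 15
        np.testing.assert_allclose(
            out.assays["centered"], [[-1.5, -0.5, -5.0], [0.5, 1.5, 5.0]]
        )
        calls = [
            tm.VerbCall("group_by", tuple(tm.parse_items("cols(grp)"))),
            tm.VerbCall("mutate", tuple(tm.parse_items("centered = counts - mean(counts)"))),
        ]
        assert_containers_equal(tm.ungroup(out), tm.oracle_chain(obj, calls))

    def test_sequential_cross_context_items(self, small):
        out = tm.mutate(small, "rows(kb = length / 1000), scaled = counts * .rows$kb")
        np.testing.assert_allclose(
            out.assays["scaled"],
            small.assays["counts"] * (small.row_data["length"].to_numpy() / 1000)[:, None],
        )

    def test_overwrite_is_identity_for_x_eq_x(self, small):
        for item in ("counts = counts", "rows(length = length)", "cols(grp = grp)"):
            assert_containers_equal(tm.mutate(small, item), small, rtol=0, atol=0)

    def test_unnamed_item_rejected(self, small):
        with pytest.raises(tm.TidymatError, match="must be named"):
            tm.mutate(small, "counts * 2")

    def test_reserved_name_rejected(self, small):
        with pytest.raises(tm.TidymatError, match="reserved pronoun"):
            tm.mutate(small, **{"rows": "counts * 2"})

    def test_size_stability_enforced(self, small):
        with pytest.raises(tm.SizeStabilityError, match="assays"):
            tm.mutate(small, "bad = row_means(counts)")

    def test_scalar_recycles(self, small):
        out = tm.mutate(small, "flag = 1")
        np.testing.assert_array_equal(out.assays["flag"], np.ones((3, 2)))


class TestFilter:
    def test_rows_predicate(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1], [2], [3]]}, row_data={"len": [100, 5000, 200]}
        )
        out = tm.filter(obj, "rows(len < 1000)")
        assert tm.dims(out) == (2, 1)
        np.testing.assert_array_equal(out.assays["counts"], [[1], [3]])

    def test_rows_and_cols_together(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1, 2], [3, 4], [5, 6]]},
            row_data={"len": [100, 5000, 200]},
            col_data={"grp": ["a", "b"]},
        )
        out = tm.filter(obj, 'rows(len < 1000), cols(grp == "a")')
        assert tm.dims(out) == (2, 1)

    def test_assays_predicate_rejected(self, small):
        with pytest.raises(tm.ContextError, match="only defined on rows or cols"):
            tm.filter(small, "counts > 5")

    def test_all_true_identity(self, small):
        assert_containers_equal(tm.filter(small, "rows(TRUE)"), small, rtol=0, atol=0)

    def test_all_false_empties_and_validates(self, small):
        out = tm.filter(small, "rows(FALSE)")
        assert tm.dims(out) == (0, 2)
        tm.validate(out)

    def test_predicates_combine_with_and(self, small):
        out = tm.filter(small, "rows(length > 150), rows(length < 1000)")
        assert tm.dims(out) == (1, 2)
        assert out.row_names == ["g3"]

    def test_missing_predicate_drops_record(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1], [2], [3]]}, row_data={"x": [1.0, np.nan, 3.0]}
        )
        out = tm.filter(obj, "rows(x / x >= 0)")
        assert tm.dims(out) == (2, 1)

    def test_grouping_recomputed_on_survivors(self, small):
        g = tm.group_by(small, "cols(grp)")
        out = tm.filter(g, 'cols(grp == "a")')
        assert out.col_grouping is not None
        assert out.col_grouping.keys == [("a",)]


class TestSelect:
    def test_assay_selection(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": np.ones((1, 1)), "tpm": np.zeros((1, 1))}
        )
        out = tm.select(obj, "counts")
        assert list(out.assays) == ["counts"]

    def test_rows_selection(self, small):
        obj = tm.mutate(small, "rows(extra = length * 2)")
        out = tm.select(obj, "rows(length)")
        assert list(out.row_data.columns) == ["length"]
        assert list(out.assays) == ["counts"]  # untargeted context untouched

    def test_unknown_name(self, small):
        with pytest.raises(tm.UnresolvedSymbolError, match="no assay named 'nope'"):
            tm.select(small, "nope")

    def test_grouping_variables_retained(self, small):
        g = tm.group_by(tm.mutate(small, "cols(extra = lib_size * 2)"), "cols(grp)")
        out = tm.select(g, "cols(extra)")
        assert list(out.col_data.columns) == ["extra", "grp"]


class TestArrange:
    def test_rows_ascending(self):
        obj = tm.make_annotated_matrix(
            assays={"a": [[1], [2], [3]]}, row_data={"len": [30, 10, 20]}
        )
        out = tm.arrange(obj, "rows(len)")
        np.testing.assert_array_equal(out.row_data["len"], [10, 20, 30])
        np.testing.assert_array_equal(out.assays["a"], [[2], [3], [1]])

    def test_all_equal_keys_is_identity(self, small):
        out = tm.arrange(small, "rows(0)")
        assert_containers_equal(out, small, rtol=0, atol=0)

    def test_desc_cols(self):
        obj = tm.make_annotated_matrix(
            assays={"a": [[1, 2]]}, col_data={"lib_size": [1, 2]}
        )
        out = tm.arrange(obj, "cols(desc(lib_size))")
        np.testing.assert_array_equal(out.assays["a"], [[2, 1]])

    def test_stability_on_ties(self):
        obj = tm.make_annotated_matrix(
            assays={"a": [[1], [2], [3], [4]]}, row_data={"k": [1, 0, 1, 0]}
        )
        out = tm.arrange(obj, "rows(k)")
        np.testing.assert_array_equal(out.assays["a"][:, 0], [2, 4, 1, 3])

    def test_assays_key_rejected(self, small):
        with pytest.raises(tm.ContextError, match="rows or cols"):
            tm.arrange(small, "counts")


class TestGroupBy:
    def test_col_partition_first_appearance(self):
        obj = tm.make_annotated_matrix(
            assays={"a": [[1, 2, 3]]}, col_data={"grp": ["a", "b", "a"]}
        )
        out = tm.group_by(obj, "cols(grp)")
        assert out.col_grouping.keys == [("a",), ("b",)]
        np.testing.assert_array_equal(out.col_grouping.partition[0][1], [0, 2])
        np.testing.assert_array_equal(out.col_grouping.partition[1][1], [1])

    def test_both_axes_independent(self, small):
        g = tm.group_by(small, "rows(length), cols(grp)")
        assert g.row_grouping is not None and g.col_grouping is not None

    def test_assays_grouping_rejected(self, small):
        with pytest.raises(tm.ContextError, match="partition rows or columns"):
            tm.group_by(small, "counts > 100")

    def test_regroup_replaces_same_axis(self, small):
        g1 = tm.group_by(small, "cols(grp)")
        g2 = tm.group_by(g1, "cols(lib_size)")
        assert g2.col_grouping.variables == ("lib_size",)

    def test_expression_key_materializes(self, small):
        g = tm.group_by(small, "rows(short = length < 1000)")
        assert "short" in g.row_data.columns
        assert g.row_grouping.variables == ("short",)

    def test_ungroup_roundtrip_identity(self, small):
        out = tm.ungroup(tm.group_by(small, "cols(grp)"))
        assert out.col_grouping is None
        assert_containers_equal(out, small, rtol=0, atol=0)

    def test_partial_ungroup(self, small):
        g = tm.group_by(small, "rows(length), cols(grp)")
        out = tm.ungroup(g, axes={"rows"})
        assert out.row_grouping is None and out.col_grouping is not None


class TestEffectivePartition:
    def test_cross_product_in_assays(self):
        obj = tm.make_annotated_matrix(
            assays={"a": np.arange(9).reshape(3, 3)},
            row_data={"rg": ["A", "A", "B"]},
            col_data={"cg": ["x", "y", "y"]},
        )
        g = tm.group_by(obj, "rows(rg), cols(cg)")
        blocks = tm.effective_partition(g, Context.ASSAYS)
        assert len(blocks) == 4
        got = [(tuple(r), tuple(c)) for r, c in blocks]
        assert got == [((0, 1), (0,)), ((0, 1), (1, 2)), ((2,), (0,)), ((2,), (1, 2))]

    def test_rows_context_drops_col_grouping(self):
        obj = tm.make_annotated_matrix(
            assays={"a": np.arange(9).reshape(3, 3)},
            row_data={"rg": ["A", "A", "B"]},
            col_data={"cg": ["x", "y", "y"]},
        )
        g = tm.group_by(obj, "rows(rg), cols(cg)")
        blocks = tm.effective_partition(g, Context.ROWS)
        assert len(blocks) == 2
        for _, ci in blocks:
            np.testing.assert_array_equal(ci, [0, 1, 2])

    def test_ungrouped_single_block(self, small):
        for ctx in Context:
            blocks = tm.effective_partition(small, ctx)
            assert len(blocks) == 1
            ri, ci = blocks[0]
            assert len(ri) == 3 and len(ci) == 2


class TestSummarize:
    def test_ungrouped_full_reduction(self):
        obj = tm.make_annotated_matrix(assays={"counts": [[1, 2], [3, 4]]})
        out = tm.summarize(obj, "total = sum(counts)")
        assert tm.dims(out) == (1, 1)
        np.testing.assert_array_equal(out.assays["total"], [[10]])

    def test_row_group_blocks(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1], [2], [3]]}, row_data={"g": ["A", "A", "B"]}
        )
        out = tm.summarize(tm.group_by(obj, "rows(g)"), "s = sum(counts)")
        np.testing.assert_array_equal(out.assays["s"], [[3], [3]])
        assert list(out.row_data["g"]) == ["A", "B"]

    def test_cols_item_grouped_mean(self):
        obj = tm.make_annotated_matrix(
            assays={"a": [[0, 0, 0]]},
            col_data={"grp": ["a", "a", "b"], "lib_size": [2.0, 4.0, 9.0]},
        )
        out = tm.summarize(tm.group_by(obj, "cols(grp)"), "cols(m = mean(lib_size))")
        assert tm.dims(out) == (1, 2)
        np.testing.assert_allclose(out.col_data["m"], [3.0, 9.0])

    def test_result_is_ungrouped(self, small):
        out = tm.summarize(tm.group_by(small, "cols(grp)"), "t = sum(counts)")
        assert out.row_grouping is None and out.col_grouping is None

    def test_non_scalar_result_rejected(self, small):
        with pytest.raises(tm.SizeStabilityError, match="single value"):
            tm.summarize(small, "bad = counts * 2")

    def test_non_grouping_metadata_dropped(self, small):
        out = tm.summarize(tm.group_by(small, "cols(grp)"), "t = sum(counts)")
        assert list(out.col_data.columns) == ["grp"]
        assert list(out.row_data.columns) == []


class TestPull:
    def test_assay(self, small):
        got = tm.pull(small, "counts")
        np.testing.assert_array_equal(got, small.assays["counts"])
        got[0, 0] = 99  # mutation must not write through
        assert small.assays["counts"][0, 0] == 2

    def test_rows_vector(self, small):
        np.testing.assert_array_equal(tm.pull(small, "length", "rows"), [100, 5000, 200])

    def test_unknown(self, small):
        with pytest.raises(tm.UnresolvedSymbolError, match="nope"):
            tm.pull(small, "nope", "cols")


def test_slice_equivalent_positional_filter(small):
    out = tm.filter(small, "rows(row_number() <= 2)")
    assert tm.dims(out) == (2, 2)
    assert out.row_names == ["g1", "g2"]
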