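import numpy as np
import pandas as pd
import pytest

import tidymat as tm
from tidymat.core_model import GroupingSpec


class TestConstructor:
    def test_valid_2x2(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[1, 2], [3, 4]]},
            row_data={"len": [10, 20]},
            col_data={"grp": ["a", "b"]},
        )
        assert tm.dims(obj) == (2, 2)
        assert list(obj.assays) == ["counts"]
        assert obj.row_grouping is None and obj.col_grouping is None

    def test_row_data_length_mismatch(self):
        with pytest.raises(tm.ValidationError, match="row_data length mismatch"):
            tm.make_annotated_matrix(
                assays={"counts": [[1, 2], [3, 4]]},
                row_data={"len": [10, 20, 30]},
            )

    def test_empty_container(self):
        obj = tm.make_annotated_matrix(assays={}, shape=(0, 0))
        assert tm.dims(obj) == (0, 0)
        assert len(obj.row_data) == 0 and len(obj.col_data) == 0

    def test_assay_shape_mismatch(self):
        with pytest.raises(tm.ValidationError, match="assay 'tpm'"):
            tm.make_annotated_matrix(
                assays={"counts": np.zeros((3, 2)), "tpm": np.zeros((3, 3))}
            )

    def test_duplicate_column_names(self):
        df = pd.DataFrame(np.ones((2, 2)), columns=["x", "x"])
        with pytest.raises(tm.ValidationError, match="duplicate name in rows context"):
            tm.make_annotated_matrix(assays={"a": np.zeros((2, 2))}, row_data=df)

    def test_non_unique_names(self):
        with pytest.raises(tm.ValidationError, match="row_names are not unique"):
            tm.make_annotated_matrix(
                assays={"a": np.zeros((2, 2))}, row_names=["g", "g"]
            )

    def test_object_assay_rejected(self):
        with pytest.raises(tm.ValidationError, match="unsupported element type"):
            tm.make_annotated_matrix(assays={"a": np.array([["x", "y"]], dtype=object)})

    def test_cross_context_name_collision_allowed(self):
        obj = tm.make_annotated_matrix(
            assays={"score": np.ones((2, 1))},
            row_data={"score": [1, 2]},
            col_data={"score": [3]},
        )
        assert tm.dims(obj) == (2, 1)


class TestValidate:
    def test_identity_on_valid(self, small):
        assert tm.validate(small) is small

    def test_names_offending_assay(self, small):
        small.assays["extra"] = np.zeros((3, 3))
        with pytest.raises(tm.ValidationError, match="assay 'extra' has shape 3x3"):
            tm.validate(small)

    def test_collects_multiple_diagnostics(self, small):
        small.assays["extra"] = np.zeros((3, 3))
        small.row_names = ["a", "a", "b"]
        with pytest.raises(tm.ValidationError, match="extra.*not unique"):
            tm.validate(small)

    def test_grouping_partition_checked(self, small):
        bad = GroupingSpec(
            axis="rows", variables=("length",),
            partition=((("k",), np.array([0, 1])),),  # misses index 2
        )
        small.row_grouping = bad
        with pytest.raises(tm.ValidationError, match="does not partition"):
            tm.validate(small)


class TestDims:
    def test_fixture(self, small):
        assert tm.dims(small) == (3, 2)

    def test_empty(self):
        assert tm.dims(tm.make_annotated_matrix(shape=(0, 0))) == (0, 0)

    def test_after_filter(self, small):
        out = tm.filter(small, "rows(length < 1000)")
        assert tm.dims(out) == (2, 2)


class TestGroupingSpec:
    def test_first_appearance_order(self):
        df = pd.DataFrame({"g": ["b", "a", "b", "a"]})
        spec = GroupingSpec.from_metadata(df, ["g"], "rows")
        assert spec.keys == [("b",), ("a",)]
        np.testing.assert_array_equal(spec.partition[0][1], [0, 2])
        np.testing.assert_array_equal(spec.partition[1][1], [1, 3])

    def test_missing_values_form_own_group(self):
        df = pd.DataFrame({"g": ["a", np.nan, "a", np.nan]})
        spec = GroupingSpec.from_metadata(df, ["g"], "rows")
        assert len(spec.partition) == 2
        np.testing.assert_array_equal(spec.partition[1][1], [1, 3])

    def test_unknown_variable(self):
        with pytest.raises(tm.ValidationError, match="nope"):
            GroupingSpec.from_metadata(pd.DataFrame({"g": [1]}), ["nope"], "rows")


def test_verbs_preserve_validity(small):
    outs = [
        tm.mutate(small, "x = counts * 2"),
        tm.filter(small, "rows(length < 1000)"),
        tm.select(small, "counts"),
        tm.arrange(small, "rows(length)"),
        tm.group_by(small, "cols(grp)"),
        tm.summarize(small, "t = sum(counts)"),
        tm.ungroup(small),
    ]
    for out in outs:
        tm.validate(out)
        for m in out.assays.values():
            assert m.shape == out.shape
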