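import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tidymat as tm
from tidymat.core_model import Context
from tidymat.language import parse_expr
from tidymat.masks import (
    broadcast_col_to_assay,
    broadcast_row_to_assay,
    build_frame,
    check_size_stable,
    evaluate,
    slice_assay_to_cols,
    slice_assay_to_rows,
)


class TestBroadcast:
    def test_row_to_assay(self):
        np.testing.assert_array_equal(
            broadcast_row_to_assay([1, 2, 3], 2), [[1, 1], [2, 2], [3, 3]]
        )

    def test_row_empty(self):
        assert broadcast_row_to_assay([], 4).shape == (0, 4)

    def test_row_singleton(self):
        np.testing.assert_array_equal(broadcast_row_to_assay([5], 1), [[5]])

    def test_col_to_assay(self):
        np.testing.assert_array_equal(
            broadcast_col_to_assay([10, 20], 2), [[10, 20], [10, 20]]
        )

    def test_col_single(self):
        np.testing.assert_array_equal(broadcast_col_to_assay([7], 3), [[7], [7], [7]])

    def test_col_empty(self):
        assert broadcast_col_to_assay([], 2).shape == (2, 0)


class TestSlice:
    def test_rows(self):
        out = slice_assay_to_rows(np.array([[1, 2], [3, 4]]))
        assert len(out) == 2
        np.testing.assert_array_equal(out[0], [1, 2])
        np.testing.assert_array_equal(out[1], [3, 4])

    def test_rows_empty(self):
        assert slice_assay_to_rows(np.empty((0, 3))) == []

    def test_rows_single(self):
        out = slice_assay_to_rows(np.array([[1, 2, 3]]))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0], [1, 2, 3])

    def test_cols(self):
        out = slice_assay_to_cols(np.array([[1, 2], [3, 4]]))
        np.testing.assert_array_equal(out[0], [1, 3])
        np.testing.assert_array_equal(out[1], [2, 4])

    def test_cols_empty(self):
        assert slice_assay_to_cols(np.empty((3, 0))) == []

    def test_cols_column_vector(self):
        out = slice_assay_to_cols(np.array([[1], [2]]))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0], [1, 2])


@settings(max_examples=200, deadline=None)
@given(
    v=arrays(np.float64, st.integers(0, 20), elements=st.floats(-1e6, 1e6)),
    p=st.integers(0, 8),
)
def test_roundtrip_slice_of_broadcast(v, p):
    rows = slice_assay_to_rows(broadcast_row_to_assay(v, p))
    assert len(rows) == len(v)
    for i, row in enumerate(rows):
        np.testing.assert_array_equal(row, np.full(p, v[i]))


@settings(max_examples=200, deadline=None)
@given(
    v=arrays(np.float64, st.integers(0, 20), elements=st.floats(-1e6, 1e6)),
    n=st.integers(0, 8),
)
def test_transpose_duality(v, n):
    np.testing.assert_array_equal(
        broadcast_col_to_assay(v, n), broadcast_row_to_assay(v, n).T
    )


class TestFrames:
    def test_assays_frame_reshaped_rows_pronoun(self, small):
        frame = build_frame(small, Context.ASSAYS)
        got = frame.resolve_pronoun(Context.ROWS, "reshaped", "length")
        want = broadcast_row_to_assay(small.row_data["length"].to_numpy(), 2)
        np.testing.assert_array_equal(got, want)

    def test_rows_frame_reshaped_assay_pronoun(self, small):
        frame = build_frame(small, Context.ROWS)
        got = frame.resolve_pronoun(Context.ASSAYS, "reshaped", "counts")
        want = slice_assay_to_rows(small.assays["counts"])
        assert len(got) == len(want)
        for a, b in zip(got, want):
            np.testing.assert_array_equal(a, b)

    def test_cols_frame_asis_assay_pronoun(self, small):
        frame = build_frame(small, Context.COLS)
        got = frame.resolve_pronoun(Context.ASSAYS, "asis", "counts")
        np.testing.assert_array_equal(got, small.assays["counts"])

    def test_laziness_no_pronoun_no_reshape(self, small):
        frame = build_frame(small, Context.ASSAYS)
        evaluate(parse_expr("counts * 2"), frame)
        assert frame.reshape_count == 0

    def test_memoization_single_reshape(self, small):
        frame = build_frame(small, Context.ASSAYS)
        evaluate(parse_expr(".rows$length + .rows$length"), frame)
        assert frame.reshape_count == 1

    def test_resolution_order_mask_first(self, small):
        frame = build_frame(small, Context.ROWS, caller_fallback={"length": np.array([0, 0, 0])})
        np.testing.assert_array_equal(evaluate(parse_expr("length"), frame), [100, 5000, 200])

    def test_caller_fallback_used_when_unbound(self, small):
        frame = build_frame(small, Context.ROWS, caller_fallback={"threshold": 300})
        np.testing.assert_array_equal(
            evaluate(parse_expr("length < threshold"), frame), [True, False, True]
        )

    def test_metadata_to_metadata_reshape_is_error(self, small):
        frame = build_frame(small, Context.ROWS)
        with pytest.raises(tm.ContextError, match="_asis"):
            frame.resolve_pronoun(Context.COLS, "reshaped", "lib_size")


class TestEvaluate:
    def test_counts_divided_by_row_pronoun(self):
        # independently derived with the long-form oracle (see test_oracle)
        obj = tm.make_annotated_matrix(
            assays={"counts": [[2, 4], [6, 8]]}, row_data={"len": [1, 2]}
        )
        frame = build_frame(obj, Context.ASSAYS)
        got = evaluate(parse_expr("counts / .rows$len"), frame)
        np.testing.assert_allclose(got, [[2, 4], [3, 4]])
        ref = tm.oracle_chain(
            obj, [tm.VerbCall("mutate", tuple(tm.parse_items("q = counts / .rows$len")))]
        ).assays["q"]
        np.testing.assert_allclose(got, ref)

    def test_log1p_closed_form(self):
        obj = tm.make_annotated_matrix(
            assays={"counts": [[0.0, 1.0], [np.e - 1, np.e**2 - 1]]}
        )
        got = evaluate(parse_expr("log1p(counts)"), build_frame(obj, Context.ASSAYS))
        np.testing.assert_allclose(got, [[0.0, np.log(2.0)], [1.0, 2.0]])

    def test_unresolved_symbol_names_symbol(self, small):
        frame = build_frame(small, Context.ASSAYS)
        with pytest.raises(tm.UnresolvedSymbolError, match="'weights'.*assays"):
            evaluate(parse_expr("counts * weights"), frame)

    def test_unknown_function_rejected(self, small):
        frame = build_frame(small, Context.ASSAYS)
        with pytest.raises(tm.TidymatError, match="unknown function 'system'"):
            evaluate(parse_expr("system(counts)"), frame)

    def test_register_function_extends_whitelist(self, small):
        tm.register_function("double_it", lambda x: np.asarray(x) * 2)
        try:
            frame = build_frame(small, Context.ASSAYS)
            got = evaluate(parse_expr("double_it(counts)"), frame)
            np.testing.assert_array_equal(got, small.assays["counts"] * 2)
        finally:
            from tidymat.masks import FUNCTIONS
            del FUNCTIONS["double_it"]

    def test_logical_promoted_under_arithmetic(self, small):
        frame = build_frame(small, Context.ASSAYS)
        got = evaluate(parse_expr("(counts > 3) + (counts > 3)"), frame)
        assert got.dtype.kind == "i"


class TestSizeStability:
    def test_scalar_recycled(self):
        np.testing.assert_array_equal(
            check_size_stable(0, Context.ROWS, (3,)), [0, 0, 0]
        )

    def test_wrong_matrix_shape(self):
        with pytest.raises(tm.SizeStabilityError, match="got 2x2, want 3x2"):
            check_size_stable(np.zeros((2, 2)), Context.ASSAYS, (3, 2))

    def test_exact_vector_passes(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(check_size_stable(v, Context.ROWS, (3,)), v)

    def test_partial_recycling_rejected(self):
        with pytest.raises(tm.SizeStabilityError):
            check_size_stable(np.array([1.0, 2.0]), Context.ROWS, (4,))
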