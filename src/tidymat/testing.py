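"""Test helpers: container comparison and a random verb-chain generator.

Used by the package's own suite and by the acceptance script to drive
the masked-path vs unwound-path equivalence checks.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .core_model import AnnotatedMatrix, Context
from .io import generate_fixture
from .language import parse_items
from .verbs import VerbCall

__all__ = ["assert_containers_equal", "random_fixture", "random_chain"]


def _numeric_close(a: np.ndarray, b: np.ndarray, rtol: float, atol: float) -> bool:
    return bool(np.allclose(a.astype(float), b.astype(float), rtol=rtol, atol=atol, equal_nan=True))


def _values_equal(a: np.ndarray, b: np.ndarray, rtol: float, atol: float, where: str) -> None:
    if a.shape != b.shape:
        raise AssertionError(f"{where}: shape {a.shape} != {b.shape}")
    if a.dtype.kind in "bifu" and b.dtype.kind in "bifu":
        if not _numeric_close(a, b, rtol, atol):
            raise AssertionError(f"{where}: values differ\n{a}\nvs\n{b}")
        return
    aa, bb = a.astype(object), b.astype(object)
    for i in range(aa.size):
        x, y = aa.ravel()[i], bb.ravel()[i]
        both_na = pd.isna(x) is True and pd.isna(y) is True
        if not both_na and x != y:
            raise AssertionError(f"{where}[{i}]: {x!r} != {y!r}")


def assert_containers_equal(
    a: AnnotatedMatrix,
    b: AnnotatedMatrix,
    rtol: float = 1e-12,
    atol: float = 1e-12,
    check_names: bool = True,
) -> None:
    """Assert equality of all data fields (grouping state excluded)."""
    assert a.shape == b.shape, f"shape {a.shape} != {b.shape}"
    assert list(a.assays) == list(b.assays), f"assay names {list(a.assays)} != {list(b.assays)}"
    for name in a.assays:
        _values_equal(a.assays[name], b.assays[name], rtol, atol, f"assay '{name}'")
    for ctx, ta, tb in (("rows", a.row_data, b.row_data), ("cols", a.col_data, b.col_data)):
        assert list(ta.columns) == list(tb.columns), (
            f"{ctx} variables {list(ta.columns)} != {list(tb.columns)}"
        )
        for col in ta.columns:
            _values_equal(ta[col].to_numpy(), tb[col].to_numpy(), rtol, atol, f"{ctx}${col}")
    if check_names:
        assert a.row_names == b.row_names, "row names differ"
        assert a.col_names == b.col_names, "col names differ"


def random_fixture(rng: np.random.Generator, max_n: int = 40, max_p: int = 12) -> AnnotatedMatrix:
    """A random small fixture (dims >= 1 so the long form is faithful)."""
    n = int(rng.integers(1, max_n + 1))
    p = int(rng.integers(1, max_p + 1))
    n_assays = int(rng.integers(1, 4))
    return generate_fixture(
        n, p, n_assays=n_assays, n_row_vars=3, n_col_vars=3,
        seed=int(rng.integers(0, 2**31)),
    )


def _items(text: str) -> tuple:
    return tuple(parse_items(text))


class _Schema:
    """Tracks variable names available to the chain generator."""

    def __init__(self, obj: AnnotatedMatrix):
        self.assays = list(obj.assays)
        self.row_num = [c for c in obj.row_data.columns
                        if obj.row_data[c].dtype.kind in "if"]
        self.row_cat = [c for c in obj.row_data.columns
                        if obj.row_data[c].dtype.kind not in "if"]
        self.col_num = [c for c in obj.col_data.columns
                        if obj.col_data[c].dtype.kind in "if"]
        self.col_cat = [c for c in obj.col_data.columns
                        if obj.col_data[c].dtype.kind not in "if"]
        self.counter = 0

    def fresh(self, prefix: str) -> str:
        self.counter += 1
        return f"{prefix}{self.counter}"


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(0, len(options)))]


def _assay_expr(rng: np.random.Generator, s: _Schema) -> str:
    a = _pick(rng, s.assays)
    templates = [
        f"log1p({a})",
        f"{a} * 2 + 1",
        f"{a} - mean({a})",
        f"{a} / (sum({a}) + 1)",
        f"sqrt(abs({a}))",
        f"if_else({a} > mean({a}), {a}, 0)",
        f"{a} + n()",
    ]
    if s.row_num:
        v = _pick(rng, s.row_num)
        templates += [f"{a} / (.rows${v} + 1)", f"{a} + .rows${v}"]
    if s.col_num:
        v = _pick(rng, s.col_num)
        templates += [f"{a} / (.cols${v} + 1)", f"{a} * .cols${v}"]
    if len(s.assays) > 1:
        b = _pick(rng, s.assays)
        templates.append(f"{a} + {b}")
    return _pick(rng, templates)


def _axis_expr(rng: np.random.Generator, numeric: list[str], axiswise: str, assay: str) -> str:
    v = _pick(rng, numeric)
    templates = [
        f"{v} - mean({v})",
        f"{v} * 2",
        f"abs({v}) + 1",
        f"{v} / (sd({v}) + 1)",
        f"{v} - median({v})",
        f"{axiswise}(.assays_asis${assay})",
        f"map_dbl(.assays${assay}, mean)",
    ]
    return _pick(rng, templates)


def random_chain(
    rng: np.random.Generator, obj: AnnotatedMatrix, max_len: int = 5
) -> list[VerbCall]:
    """A random verb chain valid for ``obj``'s schema.

    Draws from mutate / filter / arrange / group_by / summarize with
    expressions over the registered whitelist; summarize, when drawn,
    ends the chain.
    """
    s = _Schema(obj)
    length = int(rng.integers(1, max_len + 1))
    calls: list[VerbCall] = []
    for _ in range(length):
        verb = _pick(rng, ["mutate", "mutate", "filter", "arrange", "group_by", "summarize"])
        if verb == "mutate":
            which = _pick(rng, ["assays", "rows", "cols"])
            if which == "assays":
                name = s.fresh("m")
                calls.append(VerbCall("mutate", _items(f"{name} = {_assay_expr(rng, s)}")))
                s.assays.append(name)
            elif which == "rows":
                name = s.fresh("r")
                expr = _axis_expr(rng, s.row_num, "row_means", _pick(rng, s.assays))
                calls.append(VerbCall("mutate", _items(f"rows({name} = {expr})")))
                s.row_num.append(name)
            else:
                name = s.fresh("c")
                expr = _axis_expr(rng, s.col_num, "col_means", _pick(rng, s.assays))
                calls.append(VerbCall("mutate", _items(f"cols({name} = {expr})")))
                s.col_num.append(name)
        elif verb == "filter":
            if rng.random() < 0.5 and s.row_num:
                v = _pick(rng, s.row_num)
                pred = _pick(rng, [
                    f"{v} <= median({v})",
                    f"{v} >= mean({v})",
                    f"row_number() <= {int(rng.integers(1, 30))}",
                ])
                calls.append(VerbCall("filter", _items(f"rows({pred})")))
            elif s.col_num:
                v = _pick(rng, s.col_num)
                pred = _pick(rng, [
                    f"{v} <= median({v})",
                    f"row_number() <= {int(rng.integers(1, 10))}",
                ])
                calls.append(VerbCall("filter", _items(f"cols({pred})")))
        elif verb == "arrange":
            if rng.random() < 0.5 and s.row_num:
                v = _pick(rng, s.row_num)
                key = f"desc({v})" if rng.random() < 0.5 else v
                calls.append(VerbCall("arrange", _items(f"rows({key})")))
            elif s.col_num:
                v = _pick(rng, s.col_num)
                calls.append(VerbCall("arrange", _items(f"cols({v})")))
        elif verb == "group_by":
            parts = []
            if s.row_cat and rng.random() < 0.7:
                parts.append(f"rows({_pick(rng, s.row_cat)})")
            if s.col_cat and (not parts or rng.random() < 0.5):
                parts.append(f"cols({_pick(rng, s.col_cat)})")
            if parts:
                calls.append(VerbCall("group_by", _items(", ".join(parts))))
        else:  # summarize ends the chain
            a = _pick(rng, s.assays)
            parts = [f"{s.fresh('t')} = {_pick(rng, ['sum', 'mean', 'max'])}({a})"]
            if s.row_num and rng.random() < 0.5:
                parts.append(f"rows({s.fresh('rs')} = mean({_pick(rng, s.row_num)}))")
            if s.col_num and rng.random() < 0.5:
                parts.append(f"cols({s.fresh('cs')} = sum({_pick(rng, s.col_num)}))")
            calls.append(VerbCall("summarize", _items(", ".join(parts))))
            break
    if not calls:
        calls.append(VerbCall("mutate", _items(f"m0 = log1p({s.assays[0]})")))
    return calls
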