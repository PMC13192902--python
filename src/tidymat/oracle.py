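"""Long-form reference semantics: unwind, rewind, and tidy verb oracles.

The container can be flattened ("unwound") into a long table with one
record per assay cell, replicating row metadata down each column block
and column metadata across each row block.  Records are ordered
column-major: all rows of column 1, then column 2, and so on; indices
are 1-based.

Verbs have plain tidy counterparts on this representation — grouped
operations group the long table by the grouping variables, with
assays-context grouped operations grouping by both axes' variables
simultaneously.  The equivalence

    verb(obj)  ==  rewind(verb'(unwind(obj)))

is the package's principal correctness property.  This path is
deliberately naive and slow; it exists for correctness, not speed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any, Callable, Iterable

import numpy as np
import pandas as pd

from .core_model import (
    AnnotatedMatrix,
    Context,
    ContextError,
    TidymatError,
    _hashable,
    make_annotated_matrix,
)
from .masks import CallExpr, Expression, Lit, Pronoun, Sym

__all__ = [
    "LongTable",
    "unwind",
    "rewind",
    "write_long_tsv",
    "read_long_tsv",
    "OracleUnsupported",
    "oracle_chain",
]

_RESERVED_COLUMNS = {"row_index", "col_index", "row_name", "col_name"}


class OracleUnsupported(TidymatError):
    """The long-form oracle does not model this expression form."""


@dataclasses.dataclass
class LongTable:
    """The unwound one-record-per-assay-cell form of a container.

    ``assay_cols`` / ``row_var_cols`` / ``col_var_cols`` map original
    variable names to their (possibly suffix-disambiguated) long-table
    column names.
    """

    records: pd.DataFrame
    n: int
    p: int
    assay_cols: dict[str, str]
    row_var_cols: dict[str, str]
    col_var_cols: dict[str, str]
    row_names_present: bool
    col_names_present: bool

    @property
    def columns(self) -> list[str]:
        return list(self.records.columns)


def _disambiguate(name: str, taken: set[str], suffix: str) -> str:
    if name not in taken:
        return name
    new = f"{name}{suffix}"
    warnings.warn(
        f"metadata variable '{name}' collides with another long-table column; "
        f"renamed to '{new}'",
        stacklevel=3,
    )
    return new


def unwind(obj: AnnotatedMatrix) -> LongTable:
    """Flatten a container to its long form (column-major record order)."""
    n, p = obj.shape
    data: dict[str, Any] = {
        "row_index": np.tile(np.arange(1, n + 1), p),
        "col_index": np.repeat(np.arange(1, p + 1), n),
    }
    if obj.row_names is not None:
        data["row_name"] = np.tile(np.asarray(obj.row_names, dtype=object), p)
    if obj.col_names is not None:
        data["col_name"] = np.repeat(np.asarray(obj.col_names, dtype=object), n)
    taken = set(data) | _RESERVED_COLUMNS
    assay_cols: dict[str, str] = {}
    for name, M in obj.assays.items():
        col = _disambiguate(name, taken, ".assay")
        taken.add(col)
        data[col] = M.flatten(order="F")
        assay_cols[name] = col
    row_var_cols: dict[str, str] = {}
    for v in obj.row_data.columns:
        col = _disambiguate(v, taken, ".row")
        taken.add(col)
        data[col] = np.tile(obj.row_data[v].to_numpy(), p)
        row_var_cols[v] = col
    col_var_cols: dict[str, str] = {}
    for v in obj.col_data.columns:
        col = _disambiguate(v, taken, ".col")
        taken.add(col)
        data[col] = np.repeat(obj.col_data[v].to_numpy(), n)
        col_var_cols[v] = col
    records = pd.DataFrame(data, index=pd.RangeIndex(n * p))
    return LongTable(
        records=records,
        n=n,
        p=p,
        assay_cols=assay_cols,
        row_var_cols=row_var_cols,
        col_var_cols=col_var_cols,
        row_names_present=obj.row_names is not None,
        col_names_present=obj.col_names is not None,
    )


def _na_equal(a: Any, b: Any) -> bool:
    try:
        if pd.isna(a) and pd.isna(b):
            return True
    except (TypeError, ValueError):
        pass
    return bool(a == b)


def _first_per_index(records: pd.DataFrame, index_col: str, var: str, axis_word: str) -> pd.Series:
    firsts = records.groupby(index_col, sort=True)[var].first()
    grouped = records.groupby(index_col, sort=True)[var]
    for idx, values in grouped:
        first = values.iloc[0]
        for v in values:
            if not _na_equal(v, first):
                raise TidymatError(f"{var} not constant within {axis_word} {idx}")
    return firsts


def rewind(
    tbl: LongTable,
    assay_names: Iterable[str] | None = None,
    row_vars: Iterable[str] | None = None,
    col_vars: Iterable[str] | None = None,
) -> AnnotatedMatrix:
    """Reconstruct a container from its long form.

    The inverse of :func:`unwind` on data fields; grouping state does
    not survive the round trip.  Degenerate grids with exactly one
    zero-length axis cannot carry the other axis's metadata values, so
    those come back as missing.
    """
    n, p = tbl.n, tbl.p
    assay_map = dict(tbl.assay_cols) if assay_names is None else {a: tbl.assay_cols.get(a, a) for a in assay_names}
    row_map = dict(tbl.row_var_cols) if row_vars is None else {v: tbl.row_var_cols.get(v, v) for v in row_vars}
    col_map = dict(tbl.col_var_cols) if col_vars is None else {v: tbl.col_var_cols.get(v, v) for v in col_vars}

    recs = tbl.records.sort_values(["col_index", "row_index"], kind="stable").reset_index(drop=True)
    if len(recs) != n * p:
        raise TidymatError(f"incomplete grid: {len(recs)} records for a {n}x{p} container")
    if n * p:
        want_rows = np.tile(np.arange(1, n + 1), p)
        want_cols = np.repeat(np.arange(1, p + 1), n)
        if not (np.array_equal(recs["row_index"].to_numpy(), want_rows)
                and np.array_equal(recs["col_index"].to_numpy(), want_cols)):
            raise TidymatError("incomplete grid: duplicated or missing (row_index, col_index) cells")

    assays = {
        name: recs[col].to_numpy().reshape((n, p), order="F")
        for name, col in assay_map.items()
    }

    def axis_table(index_col: str, var_map: dict[str, str], length: int, word: str) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.RangeIndex(length))
        for name, col in var_map.items():
            if len(recs):
                firsts = _first_per_index(recs, index_col, col, word)
                out[name] = firsts.reindex(np.arange(1, length + 1)).to_numpy()
            else:
                out[name] = np.full(length, np.nan)
        return out

    row_data = axis_table("row_index", row_map, n, "row")
    col_data = axis_table("col_index", col_map, p, "col")

    row_names = col_names = None
    if tbl.row_names_present and "row_name" in recs.columns and len(recs):
        row_names = list(recs.drop_duplicates("row_index").sort_values("row_index")["row_name"])
    elif tbl.row_names_present and n == 0:
        row_names = []
    if tbl.col_names_present and "col_name" in recs.columns and len(recs):
        col_names = list(recs.drop_duplicates("col_index").sort_values("col_index")["col_name"])
    elif tbl.col_names_present and p == 0:
        col_names = []

    return make_annotated_matrix(
        assays=assays,
        row_data=row_data,
        col_data=col_data,
        row_names=row_names,
        col_names=col_names,
        shape=(n, p),
    )


# --------------------------------------------------------------------------
# TSV serialization (fixed header order, "NA" missing marker)
# --------------------------------------------------------------------------

def write_long_tsv(tbl: LongTable, path: Any) -> None:
    ordered = ["row_index", "col_index"]
    if tbl.row_names_present:
        ordered.append("row_name")
    if tbl.col_names_present:
        ordered.append("col_name")
    ordered += list(tbl.assay_cols.values())
    ordered += list(tbl.row_var_cols.values())
    ordered += list(tbl.col_var_cols.values())
    tbl.records[ordered].to_csv(path, sep="\t", na_rep="NA", index=False)


def read_long_tsv(
    path: Any,
    n: int,
    p: int,
    assay_names: Iterable[str],
    row_vars: Iterable[str],
    col_vars: Iterable[str],
) -> LongTable:
    records = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    return LongTable(
        records=records,
        n=n,
        p=p,
        assay_cols={a: a for a in assay_names},
        row_var_cols={v: v for v in row_vars},
        col_var_cols={v: v for v in col_vars},
        row_names_present="row_name" in records.columns,
        col_names_present="col_name" in records.columns,
    )


# --------------------------------------------------------------------------
# Tidy-semantics verb counterparts (the oracle executor)
# --------------------------------------------------------------------------
#
# The executor keeps the long record table plus the two axis tables
# (exactly what a tidyverse user would hold as three data frames) and a
# note of which variables currently group each axis.

def _var(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float("nan") if x.size < 2 else float(((x - x.mean()) ** 2).sum() / (x.size - 1))


_O_REDUCE: dict[str, Callable[[np.ndarray], Any]] = {
    "mean": lambda x: float("nan") if np.asarray(x).size == 0 else float(np.asarray(x, dtype=float).sum() / np.asarray(x).size),
    "sum": lambda x: np.asarray(x).sum(),
    "min": lambda x: np.asarray(x).min(),
    "max": lambda x: np.asarray(x).max(),
    "median": lambda x: float(np.median(np.asarray(x, dtype=float))),
    "var": _var,
    "sd": lambda x: float(np.sqrt(_var(x))),
}

_O_ELEMENTWISE: dict[str, Callable[..., Any]] = {
    "+": lambda a, b=None: (+_p(a)) if b is None else _p(a) + _p(b),
    "-": lambda a, b=None: (-_p(a)) if b is None else _p(a) - _p(b),
    "*": lambda a, b: _p(a) * _p(b),
    "/": lambda a, b: np.true_divide(_p(a), _p(b)),
    "^": lambda a, b: np.power(_p(a), _p(b)),
    "==": lambda a, b: np.asarray(a) == np.asarray(b),
    "!=": lambda a, b: np.asarray(a) != np.asarray(b),
    "<": lambda a, b: np.asarray(a) < np.asarray(b),
    "<=": lambda a, b: np.asarray(a) <= np.asarray(b),
    ">": lambda a, b: np.asarray(a) > np.asarray(b),
    ">=": lambda a, b: np.asarray(a) >= np.asarray(b),
    "&": lambda a, b: np.asarray(a) & np.asarray(b),
    "|": lambda a, b: np.asarray(a) | np.asarray(b),
    "!": lambda a: ~np.asarray(a).astype(bool),
    "log": np.log,
    "log1p": np.log1p,
    "log2": np.log2,
    "log10": np.log10,
    "exp": np.exp,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "if_else": lambda c, y, n: np.where(np.asarray(c).astype(bool), y, n),
}


def _p(x: Any) -> Any:
    arr = np.asarray(x)
    return arr.astype(np.int64) if arr.dtype.kind == "b" else x


class _LongEnv:
    """Symbol environment for evaluating one group slice of a table.

    ``df`` is the slice; ``lookup`` maps a bare symbol to its column;
    ``pronoun`` resolves cross-context references.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        own: dict[str, str],
        pronoun_maps: dict[Context, dict[str, str]],
        records: pd.DataFrame | None = None,
        index_col: str | None = None,
        assay_cols: dict[str, str] | None = None,
    ):
        self.df = df
        self.own = own
        self.pronoun_maps = pronoun_maps
        self.records = records
        self.index_col = index_col
        self.assay_cols = assay_cols or {}

    def size(self) -> int:
        return len(self.df)

    def lookup(self, name: str) -> np.ndarray:
        if name not in self.own:
            raise OracleUnsupported(f"symbol '{name}' not a column of this context")
        return self.df[self.own[name]].to_numpy()

    def pronoun(self, ref: Pronoun) -> np.ndarray:
        mapping = self.pronoun_maps.get(ref.target)
        if mapping is None or ref.name not in mapping:
            raise OracleUnsupported(f"pronoun {ref.target.value}${ref.name} unavailable here")
        return self.df[mapping[ref.name]].to_numpy()

    def assay_rowwise(self, name: str, fn: Callable[[np.ndarray], Any]) -> np.ndarray:
        """Per-axis-element reduction of one assay, via the record table."""
        if self.records is None or self.index_col is None or name not in self.assay_cols:
            raise OracleUnsupported(f"assay '{name}' unavailable from this context")
        col = self.assay_cols[name]
        grouped = self.records.groupby(self.index_col, sort=True)[col]
        agg = grouped.apply(lambda s: fn(s.to_numpy()))
        index = self.df["__axis_index__"].to_numpy()
        return agg.reindex(index).to_numpy()


_ROWWISE = {"row_means": "mean", "row_sums": "sum"}
_COLWISE = {"col_means": "mean", "col_sums": "sum"}


def _leval(expr: Expression, env: _LongEnv, axiswise: dict[str, str]) -> Any:
    if isinstance(expr, Lit):
        return expr.value
    if isinstance(expr, Sym):
        return env.lookup(expr.name)
    if isinstance(expr, Pronoun):
        return env.pronoun(expr)
    if isinstance(expr, CallExpr):
        if expr.fn == "n":
            return env.size()
        if expr.fn == "row_number":
            return np.arange(1, env.size() + 1)
        if expr.fn in axiswise and len(expr.args) == 1 and isinstance(expr.args[0], Pronoun) \
                and expr.args[0].target is Context.ASSAYS:
            return env.assay_rowwise(expr.args[0].name, _O_REDUCE[axiswise[expr.fn]])
        if expr.fn == "map_dbl" and len(expr.args) == 2 and isinstance(expr.args[0], Pronoun) \
                and expr.args[0].target is Context.ASSAYS and isinstance(expr.args[1], Sym):
            fname = expr.args[1].name
            if fname not in _O_REDUCE:
                raise OracleUnsupported(f"map_dbl over '{fname}'")
            return env.assay_rowwise(expr.args[0].name, _O_REDUCE[fname])
        if expr.fn in _O_REDUCE:
            (arg,) = expr.args
            return _O_REDUCE[expr.fn](np.asarray(_leval(arg, env, axiswise)))
        if expr.fn in _O_ELEMENTWISE:
            args = [_leval(a, env, axiswise) for a in expr.args]
            return _O_ELEMENTWISE[expr.fn](*args)
        raise OracleUnsupported(f"function '{expr.fn}' not modelled by the oracle")
    raise TypeError(f"not an expression node: {expr!r}")


@dataclasses.dataclass
class _OracleState:
    records: pd.DataFrame
    row_tbl: pd.DataFrame  # columns: row_index, [row_name], one per row var (long names)
    col_tbl: pd.DataFrame
    assay_cols: dict[str, str]
    row_var_cols: dict[str, str]
    col_var_cols: dict[str, str]
    row_group_vars: list[str]
    col_group_vars: list[str]
    row_names_present: bool
    col_names_present: bool

    @property
    def n(self) -> int:
        return len(self.row_tbl)

    @property
    def p(self) -> int:
        return len(self.col_tbl)


def _axis_table_from_long(tbl: LongTable, obj: AnnotatedMatrix, axis: str) -> pd.DataFrame:
    index_col = "row_index" if axis == "rows" else "col_index"
    name_col = "row_name" if axis == "rows" else "col_name"
    var_map = tbl.row_var_cols if axis == "rows" else tbl.col_var_cols
    length = tbl.n if axis == "rows" else tbl.p
    if len(tbl.records):
        firsts = tbl.records.drop_duplicates(index_col).sort_values(index_col)
        out = pd.DataFrame({index_col: np.arange(1, length + 1)})
        if name_col in firsts.columns:
            out[name_col] = firsts[name_col].to_numpy()
        for col in var_map.values():
            out[col] = firsts[col].to_numpy()
        return out.reset_index(drop=True)
    # degenerate grid: fall back to the container's own tables
    meta = obj.row_data if axis == "rows" else obj.col_data
    names = obj.row_names if axis == "rows" else obj.col_names
    out = pd.DataFrame({index_col: np.arange(1, length + 1)})
    if names is not None:
        out[name_col] = list(names)
    for orig, col in var_map.items():
        out[col] = meta[orig].to_numpy()
    return out


def _init_state(obj: AnnotatedMatrix) -> _OracleState:
    tbl = unwind(obj)
    return _OracleState(
        records=tbl.records,
        row_tbl=_axis_table_from_long(tbl, obj, "rows"),
        col_tbl=_axis_table_from_long(tbl, obj, "cols"),
        assay_cols=tbl.assay_cols,
        row_var_cols=tbl.row_var_cols,
        col_var_cols=tbl.col_var_cols,
        row_group_vars=list(obj.row_grouping.variables) if obj.row_grouping else [],
        col_group_vars=list(obj.col_grouping.variables) if obj.col_grouping else [],
        row_names_present=tbl.row_names_present,
        col_names_present=tbl.col_names_present,
    )


def _group_slices(df: pd.DataFrame, by: list[str]) -> list[np.ndarray]:
    """Positional group slices in first-appearance order (NA-safe keys)."""
    if not by:
        return [np.arange(len(df), dtype=np.intp)]
    cols = [df[c].to_numpy() for c in by]
    groups: dict[tuple, list[int]] = {}
    for i in range(len(df)):
        key = tuple(_hashable(c[i]) for c in cols)
        groups.setdefault(key, []).append(i)
    return [np.asarray(v, dtype=np.intp) for v in groups.values()]


def _recycle(value: Any, length: int) -> np.ndarray:
    if np.ndim(value) == 0:
        return np.full(length, value)
    arr = np.asarray(value)
    if arr.shape != (length,):
        raise TidymatError(f"oracle result has length {arr.shape}, want {length}")
    return arr


def _grouped_transform(
    df: pd.DataFrame,
    by: list[str],
    expr: Expression,
    env_factory: Callable[[pd.DataFrame], _LongEnv],
    axiswise: dict[str, str],
) -> np.ndarray:
    pieces: list[tuple[np.ndarray, np.ndarray]] = []
    for idx in _group_slices(df, by):
        sub = df.iloc[idx]
        value = _recycle(_leval(expr, env_factory(sub), axiswise), len(idx))
        pieces.append((idx, value))
    vals = [v for _, v in pieces]
    if not vals:
        return np.empty(0)
    try:
        dtype = np.result_type(*vals)
    except TypeError:
        dtype = object
    out = np.empty(len(df), dtype=dtype)
    for idx, v in pieces:
        out[idx] = v
    return out


def _long_group_cols(state: _OracleState) -> list[str]:
    return (
        [state.row_var_cols[v] for v in state.row_group_vars]
        + [state.col_var_cols[v] for v in state.col_group_vars]
    )


def _assays_env(state: _OracleState) -> Callable[[pd.DataFrame], _LongEnv]:
    pronouns = {
        Context.ROWS: dict(state.row_var_cols),
        Context.COLS: dict(state.col_var_cols),
    }
    own = dict(state.assay_cols)
    return lambda sub: _LongEnv(sub, own, pronouns)


def _axis_env(state: _OracleState, axis: Context) -> Callable[[pd.DataFrame], _LongEnv]:
    if axis is Context.ROWS:
        own = dict(state.row_var_cols)
        index_col = "row_index"
    else:
        own = dict(state.col_var_cols)
        index_col = "col_index"

    def factory(sub: pd.DataFrame) -> _LongEnv:
        sub = sub.copy()
        sub["__axis_index__"] = sub[index_col]
        return _LongEnv(
            sub, own, {}, records=state.records, index_col=index_col,
            assay_cols=state.assay_cols,
        )

    return factory


def _axis_parts(state: _OracleState, axis: Context):
    if axis is Context.ROWS:
        return state.row_tbl, state.row_var_cols, state.row_group_vars, "row_index", _ROWWISE
    return state.col_tbl, state.col_var_cols, state.col_group_vars, "col_index", _COLWISE


def _oracle_mutate(state: _OracleState, items) -> _OracleState:
    for item in items:
        name = item.name
        if item.context is Context.ASSAYS:
            values = _grouped_transform(
                state.records, _long_group_cols(state), item.expr,
                _assays_env(state), {},
            )
            col = state.assay_cols.get(name, name)
            if col in state.records.columns and col not in state.assay_cols.values():
                col = f"{name}.assay"
            state.records[col] = values
            state.assay_cols[name] = col
        else:
            tbl, var_map, group_vars, index_col, axiswise = _axis_parts(state, item.context)
            by = [var_map[v] for v in group_vars]
            values = _grouped_transform(tbl, by, item.expr, _axis_env(state, item.context), axiswise)
            col = var_map.get(name, name)
            if col in state.records.columns and col not in var_map.values():
                col = f"{name}.{'row' if item.context is Context.ROWS else 'col'}"
            tbl[col] = values
            var_map[name] = col
            mapping = pd.Series(values, index=tbl[index_col].to_numpy())
            state.records[col] = state.records[index_col].map(mapping)
    return state


def _renumber_axis(state: _OracleState, axis: Context, keep: np.ndarray) -> None:
    """Subset/permute one axis table and remap record indices."""
    tbl, _, _, index_col, _ = _axis_parts(state, axis)
    new_tbl = tbl.iloc[keep].reset_index(drop=True)
    old_index = new_tbl[index_col].to_numpy()
    remap = {old: new for new, old in enumerate(old_index, start=1)}
    new_tbl[index_col] = np.arange(1, len(new_tbl) + 1)
    if axis is Context.ROWS:
        state.row_tbl = new_tbl
    else:
        state.col_tbl = new_tbl
    recs = state.records[state.records[index_col].isin(set(old_index))].copy()
    recs[index_col] = recs[index_col].map(remap)
    state.records = recs.sort_values(["col_index", "row_index"], kind="stable").reset_index(drop=True)


def _oracle_filter(state: _OracleState, items) -> _OracleState:
    for axis in (Context.ROWS, Context.COLS):
        mask = None
        for item in items:
            if item.context is Context.ASSAYS:
                raise ContextError("filtering is only defined on rows or cols contexts")
            if item.context is not axis:
                continue
            tbl, var_map, group_vars, _, axiswise = _axis_parts(state, axis)
            by = [var_map[v] for v in group_vars]
            values = _grouped_transform(tbl, by, item.expr, _axis_env(state, axis), axiswise)
            arr = np.asarray(values)
            if arr.dtype.kind == "f":
                arr = np.where(np.isnan(arr), 0.0, arr)
            elif arr.dtype == object:
                arr = np.where(pd.isna(arr), False, arr)
            this = arr.astype(bool)
            mask = this if mask is None else (mask & this)
        if mask is not None:
            _renumber_axis(state, axis, np.flatnonzero(mask))
    return state


def _oracle_arrange(state: _OracleState, items) -> _OracleState:
    keys: dict[Context, list[tuple[np.ndarray, bool]]] = {Context.ROWS: [], Context.COLS: []}
    for item in items:
        if item.context is Context.ASSAYS:
            raise ContextError("arrange is only defined on rows or cols contexts")
        expr, ascending = item.expr, True
        if isinstance(expr, CallExpr) and expr.fn == "desc":
            expr, ascending = expr.args[0], False
        tbl, _, _, _, axiswise = _axis_parts(state, item.context)
        values = _recycle(
            _leval(expr, _axis_env(state, item.context)(tbl), axiswise), len(tbl)
        )
        keys[item.context].append((np.asarray(values), ascending))
    for axis, ks in keys.items():
        if not ks:
            continue
        df = pd.DataFrame({i: v for i, (v, _) in enumerate(ks)})
        order = df.sort_values(
            by=list(df.columns),
            ascending=[asc for _, asc in ks],
            kind="stable",
            na_position="last",
        ).index.to_numpy()
        _renumber_axis(state, axis, order)
    return state


def _oracle_group_by(state: _OracleState, items) -> _OracleState:
    new_vars: dict[Context, list[str]] = {Context.ROWS: [], Context.COLS: []}
    for item in items:
        if item.context is Context.ASSAYS:
            raise ContextError("grouping must partition rows or columns of the matrix")
        if not isinstance(item.expr, Sym) or item.name is not None:
            raise OracleUnsupported("oracle group_by supports bare variable names only")
        new_vars[item.context].append(item.expr.name)
    if new_vars[Context.ROWS]:
        state.row_group_vars = new_vars[Context.ROWS]
    if new_vars[Context.COLS]:
        state.col_group_vars = new_vars[Context.COLS]
    return state


def _oracle_ungroup(state: _OracleState, items) -> _OracleState:
    axes = {it.context for it in items} or {Context.ROWS, Context.COLS}
    if Context.ROWS in axes:
        state.row_group_vars = []
    if Context.COLS in axes:
        state.col_group_vars = []
    return state


def _oracle_summarize(state: _OracleState, items) -> _OracleState:
    row_slices = _group_slices(state.row_tbl, [state.row_var_cols[v] for v in state.row_group_vars])
    col_slices = _group_slices(state.col_tbl, [state.col_var_cols[v] for v in state.col_group_vars])
    n2, p2 = len(row_slices), len(col_slices)

    new_row = pd.DataFrame({"row_index": np.arange(1, n2 + 1)})
    for v in state.row_group_vars:
        col = state.row_var_cols[v]
        new_row[col] = [state.row_tbl[col].to_numpy()[s[0]] for s in row_slices]
    new_col = pd.DataFrame({"col_index": np.arange(1, p2 + 1)})
    for v in state.col_group_vars:
        col = state.col_var_cols[v]
        new_col[col] = [state.col_tbl[col].to_numpy()[s[0]] for s in col_slices]

    row_index_sets = [set(state.row_tbl["row_index"].to_numpy()[s]) for s in row_slices]
    col_index_sets = [set(state.col_tbl["col_index"].to_numpy()[s]) for s in col_slices]

    new_assays: dict[str, np.ndarray] = {}
    for item in items:
        if item.context is Context.ASSAYS:
            env_factory = _assays_env(state)
            cells = []
            for rset in row_index_sets:
                for cset in col_index_sets:
                    sub = state.records[
                        state.records["row_index"].isin(rset)
                        & state.records["col_index"].isin(cset)
                    ]
                    value = _leval(item.expr, env_factory(sub), {})
                    if np.ndim(value) != 0:
                        raise TidymatError("summarize expression must reduce to one value per block")
                    cells.append(value)
            new_assays[item.name] = np.array(cells).reshape((n2, p2))
        else:
            tbl, var_map, _, _, axiswise = _axis_parts(state, item.context)
            slices = row_slices if item.context is Context.ROWS else col_slices
            env_factory = _axis_env(state, item.context)
            vals = []
            for s in slices:
                value = _leval(item.expr, env_factory(tbl.iloc[s]), axiswise)
                if np.ndim(value) != 0:
                    raise TidymatError("summarize expression must reduce to one value per block")
                vals.append(value)
            target = new_row if item.context is Context.ROWS else new_col
            target[item.name] = np.array(vals)

    row_var_cols = {v: state.row_var_cols[v] for v in state.row_group_vars}
    row_var_cols.update({it.name: it.name for it in items if it.context is Context.ROWS})
    col_var_cols = {v: state.col_var_cols[v] for v in state.col_group_vars}
    col_var_cols.update({it.name: it.name for it in items if it.context is Context.COLS})

    data: dict[str, Any] = {
        "row_index": np.tile(np.arange(1, n2 + 1), p2),
        "col_index": np.repeat(np.arange(1, p2 + 1), n2),
    }
    for name, M in new_assays.items():
        data[name] = M.flatten(order="F")
    for name, col in row_var_cols.items():
        data[col] = np.tile(new_row[col].to_numpy(), p2)
    for name, col in col_var_cols.items():
        data[col] = np.repeat(new_col[col].to_numpy(), n2)

    return _OracleState(
        records=pd.DataFrame(data, index=pd.RangeIndex(n2 * p2)),
        row_tbl=new_row,
        col_tbl=new_col,
        assay_cols={name: name for name in new_assays},
        row_var_cols=row_var_cols,
        col_var_cols=col_var_cols,
        row_group_vars=[],
        col_group_vars=[],
        row_names_present=False,
        col_names_present=False,
    )


def _state_to_container(state: _OracleState) -> AnnotatedMatrix:
    n, p = state.n, state.p
    recs = state.records.sort_values(["col_index", "row_index"], kind="stable")
    assays = {
        name: recs[col].to_numpy().reshape((n, p), order="F")
        for name, col in state.assay_cols.items()
    }
    row_data = pd.DataFrame({v: state.row_tbl[c].to_numpy() for v, c in state.row_var_cols.items()},
                            index=pd.RangeIndex(n))
    col_data = pd.DataFrame({v: state.col_tbl[c].to_numpy() for v, c in state.col_var_cols.items()},
                            index=pd.RangeIndex(p))
    row_names = list(state.row_tbl["row_name"]) if state.row_names_present and "row_name" in state.row_tbl else None
    col_names = list(state.col_tbl["col_name"]) if state.col_names_present and "col_name" in state.col_tbl else None
    return make_annotated_matrix(
        assays=assays, row_data=row_data, col_data=col_data,
        row_names=row_names, col_names=col_names, shape=(n, p),
    )


_ORACLE_VERBS = {
    "mutate": _oracle_mutate,
    "filter": _oracle_filter,
    "arrange": _oracle_arrange,
    "group_by": _oracle_group_by,
    "ungroup": _oracle_ungroup,
    "summarize": _oracle_summarize,
}


def oracle_chain(obj: AnnotatedMatrix, calls: Iterable[Any]) -> AnnotatedMatrix:
    """Run a verb chain through the unwound tidy-semantics path.

    ``calls`` is a sequence of :class:`tidymat.verbs.VerbCall`.  The
    container is unwound, each verb applied with plain long-table tidy
    semantics, and the result rewound.  Grouping state does not survive;
    compare against the ungrouped masked-path result.
    """
    state = _init_state(obj)
    for call in calls:
        if call.verb not in _ORACLE_VERBS:
            raise OracleUnsupported(f"verb '{call.verb}' not modelled by the oracle")
        state = _ORACLE_VERBS[call.verb](state, list(call.items))
    return _state_to_container(state)
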