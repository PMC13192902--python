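"""The verb layer: mutate, filter, select, arrange, group_by, summarize.

Verbs accept items either as DSL strings (``"logcounts = log1p(counts)"``,
``"rows(short = length < 1000)"``) or as pre-built :class:`Item` values.
Bare items evaluate in the assays context; ``rows(...)``/``cols(...)``
sentinels redirect them to the metadata contexts and determine where
results are stored.

Grouping only ever partitions rows or columns.  The assays context
respects both axes' partitions (cross-product blocks); each metadata
context observes only its own axis's partition.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .core_model import (
    AnnotatedMatrix,
    Context,
    ContextError,
    GroupingSpec,
    SizeStabilityError,
    TidymatError,
    UnresolvedSymbolError,
    validate,
)
from .language import RawItem, parse_expr, parse_items
from .masks import (
    CallExpr,
    Descending,
    Expression,
    Sym,
    build_frame,
    check_size_stable,
    evaluate,
)

__all__ = [
    "Item",
    "VerbCall",
    "apply_verb",
    "mutate",
    "filter",
    "select",
    "arrange",
    "group_by",
    "ungroup",
    "summarize",
    "pull",
    "effective_partition",
]

logger = logging.getLogger("tidymat")

Item = RawItem  # (context, optional name, expression)

_RESERVED = {"assays", "rows", "cols"}


@dataclasses.dataclass(frozen=True)
class VerbCall:
    verb: str
    items: tuple[Item, ...]


def _coerce_items(args: Iterable[Any], kwargs: Mapping[str, Any]) -> list[Item]:
    items: list[Item] = []
    for a in args:
        if isinstance(a, str):
            items.extend(parse_items(a))
        elif isinstance(a, RawItem):
            items.append(a)
        else:
            raise TypeError(f"cannot interpret verb argument {a!r}")
    for name, expr in kwargs.items():
        if isinstance(expr, str):
            expr = parse_expr(expr)
        items.append(Item(Context.ASSAYS, name, expr))
    return items


def _check_result_name(name: str | None, verb: str) -> str:
    if name is None:
        raise TidymatError(f"{verb} items must be named (name = expression)")
    if name.startswith(".") or name in _RESERVED:
        raise TidymatError(f"result name '{name}' collides with a reserved pronoun name")
    return name


# --------------------------------------------------------------------------
# Grouping machinery
# --------------------------------------------------------------------------

def _axis_blocks(obj: AnnotatedMatrix, axis: Context) -> list[np.ndarray]:
    spec = obj.row_grouping if axis is Context.ROWS else obj.col_grouping
    length = obj.n if axis is Context.ROWS else obj.p
    if spec is None:
        return [np.arange(length, dtype=np.intp)]
    return spec.index_lists()


def effective_partition(
    obj: AnnotatedMatrix, context: Context
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The group blocks a context observes during evaluation.

    assays -> cross product of row groups and col groups; rows -> row
    groups with the full column range; cols -> the mirror image.  An
    ungrouped axis contributes one block spanning it entirely.
    """
    full_rows = np.arange(obj.n, dtype=np.intp)
    full_cols = np.arange(obj.p, dtype=np.intp)
    if context is Context.ASSAYS:
        return [
            (ri, ci)
            for ri in _axis_blocks(obj, Context.ROWS)
            for ci in _axis_blocks(obj, Context.COLS)
        ]
    if context is Context.ROWS:
        return [(ri, full_cols) for ri in _axis_blocks(obj, Context.ROWS)]
    return [(full_rows, ci) for ci in _axis_blocks(obj, Context.COLS)]


def _expected(context: Context, ri: np.ndarray, ci: np.ndarray) -> tuple[int, ...]:
    if context is Context.ASSAYS:
        return (len(ri), len(ci))
    return (len(ri),) if context is Context.ROWS else (len(ci),)


def _alloc(shape: tuple[int, ...], pieces: list[np.ndarray]) -> np.ndarray:
    if not pieces:
        return np.empty(shape)
    try:
        dtype = np.result_type(*pieces)
    except TypeError:
        dtype = object
    return np.empty(shape, dtype=dtype)


def _eval_sized(
    obj: AnnotatedMatrix, item: Item, env: Mapping[str, Any] | None = None
) -> np.ndarray:
    """Evaluate one item per effective-partition block, stitched back.

    The result has the canonical size of the item's context: ``n x p``
    for assays, length ``n``/``p`` for the metadata contexts.
    """
    ctx = item.context
    pieces: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for ri, ci in effective_partition(obj, ctx):
        frame = build_frame(obj, ctx, env, ri, ci)
        value = evaluate(item.expr, frame)
        value = check_size_stable(value, ctx, _expected(ctx, ri, ci))
        pieces.append((ri, ci, value))
    vals = [v for _, _, v in pieces]
    if ctx is Context.ASSAYS:
        out = _alloc((obj.n, obj.p), vals)
        for ri, ci, v in pieces:
            out[np.ix_(ri, ci)] = v
        return out
    length = obj.n if ctx is Context.ROWS else obj.p
    out = _alloc((length,), vals)
    for ri, ci, v in pieces:
        idx = ri if ctx is Context.ROWS else ci
        out[idx] = v
    return out


# --------------------------------------------------------------------------
# Axis subsetting / reordering
# --------------------------------------------------------------------------

def _regroup(spec: GroupingSpec | None, table: pd.DataFrame, axis: str) -> GroupingSpec | None:
    if spec is None:
        return None
    return GroupingSpec.from_metadata(table, spec.variables, axis)


def _take(
    obj: AnnotatedMatrix,
    row_keep: np.ndarray | None = None,
    col_keep: np.ndarray | None = None,
) -> AnnotatedMatrix:
    """Slice or permute either axis, keeping every component aligned."""
    ri = np.arange(obj.n, dtype=np.intp) if row_keep is None else np.asarray(row_keep, dtype=np.intp)
    ci = np.arange(obj.p, dtype=np.intp) if col_keep is None else np.asarray(col_keep, dtype=np.intp)
    row_data = obj.row_data.iloc[ri].reset_index(drop=True)
    col_data = obj.col_data.iloc[ci].reset_index(drop=True)
    return AnnotatedMatrix(
        assays={k: v[np.ix_(ri, ci)] for k, v in obj.assays.items()},
        row_data=row_data,
        col_data=col_data,
        shape=(len(ri), len(ci)),
        row_names=[obj.row_names[i] for i in ri] if obj.row_names is not None else None,
        col_names=[obj.col_names[j] for j in ci] if obj.col_names is not None else None,
        row_grouping=_regroup(obj.row_grouping, row_data, "rows"),
        col_grouping=_regroup(obj.col_grouping, col_data, "cols"),
    )


# --------------------------------------------------------------------------
# Verbs
# --------------------------------------------------------------------------

def _mutate(obj: AnnotatedMatrix, items: list[Item], env=None) -> AnnotatedMatrix:
    out = obj.copy()
    for item in items:
        name = _check_result_name(item.name, "mutate")
        value = _eval_sized(out, item, env)
        if item.context is Context.ASSAYS:
            out.assays[name] = value
        elif item.context is Context.ROWS:
            out.row_data[name] = value
        else:
            out.col_data[name] = value
    return validate(out)


def _predicate_mask(obj: AnnotatedMatrix, item: Item, env=None) -> np.ndarray:
    values = _eval_sized(obj, item, env)
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        n_na = int(np.isnan(arr).sum())
        if n_na:
            logger.info("filter: %d record(s) dropped due to missing predicate values", n_na)
            arr = np.where(np.isnan(arr), 0.0, arr)
    elif arr.dtype == object:
        na = pd.isna(arr)
        if na.any():
            logger.info("filter: %d record(s) dropped due to missing predicate values", int(na.sum()))
            arr = np.where(na, False, arr)
    return arr.astype(bool)


def _filter(obj: AnnotatedMatrix, items: list[Item], env=None) -> AnnotatedMatrix:
    row_mask = np.ones(obj.n, dtype=bool)
    col_mask = np.ones(obj.p, dtype=bool)
    for item in items:
        if item.context is Context.ASSAYS:
            raise ContextError(
                "filtering is only defined on rows or cols contexts: element-wise "
                "matrix predicates cannot produce a valid sub-matrix"
            )
        mask = _predicate_mask(obj, item, env)
        if item.context is Context.ROWS:
            row_mask &= mask
        else:
            col_mask &= mask
    return _take(obj, np.flatnonzero(row_mask), np.flatnonzero(col_mask))


def _select(obj: AnnotatedMatrix, items: list[Item]) -> AnnotatedMatrix:
    chosen: dict[Context, list[str]] = {}
    for item in items:
        if not isinstance(item.expr, Sym) or item.name is not None:
            raise TidymatError("select items must be bare variable names")
        chosen.setdefault(item.context, []).append(item.expr.name)
    out = obj.copy()
    if Context.ASSAYS in chosen:
        for name in chosen[Context.ASSAYS]:
            if name not in obj.assays:
                raise UnresolvedSymbolError(f"no assay named '{name}'")
        out.assays = {name: out.assays[name] for name in chosen[Context.ASSAYS]}
    for ctx, attr, spec in (
        (Context.ROWS, "row_data", obj.row_grouping),
        (Context.COLS, "col_data", obj.col_grouping),
    ):
        if ctx not in chosen:
            continue
        table: pd.DataFrame = getattr(out, attr)
        keep = list(chosen[ctx])
        for name in keep:
            if name not in table.columns:
                raise UnresolvedSymbolError(f"no {ctx.value} variable named '{name}'")
        if spec is not None:  # grouping variables are implicitly retained
            keep += [v for v in spec.variables if v not in keep]
        setattr(out, attr, table[keep])
    return validate(out)


def _arrange(obj: AnnotatedMatrix, items: list[Item], env=None) -> AnnotatedMatrix:
    keys: dict[Context, list[tuple[np.ndarray, bool]]] = {Context.ROWS: [], Context.COLS: []}
    for item in items:
        if item.context is Context.ASSAYS:
            raise ContextError(
                "arrange is only defined on rows or cols contexts: ordering an "
                "axis by matrix cells cannot produce a valid sub-matrix"
            )
        frame = build_frame(obj, item.context, env)
        value = evaluate(item.expr, frame)
        ascending = True
        if isinstance(value, Descending):
            value, ascending = value.values, False
        value = check_size_stable(value, item.context, frame.expected_shape())
        keys[item.context].append((np.asarray(value), ascending))
    order: dict[Context, np.ndarray | None] = {Context.ROWS: None, Context.COLS: None}
    for ctx, ks in keys.items():
        if not ks:
            continue
        df = pd.DataFrame({i: v for i, (v, _) in enumerate(ks)})
        order[ctx] = df.sort_values(
            by=list(df.columns),
            ascending=[asc for _, asc in ks],
            kind="stable",
            na_position="last",
        ).index.to_numpy()
    return _take(obj, order[Context.ROWS], order[Context.COLS])


def _group_by(obj: AnnotatedMatrix, items: list[Item], env=None) -> AnnotatedMatrix:
    out = obj.copy()
    axis_vars: dict[Context, list[str]] = {Context.ROWS: [], Context.COLS: []}
    counter = 0
    for item in items:
        if item.context is Context.ASSAYS:
            raise ContextError(
                "grouping must partition rows or columns of the matrix; "
                "arbitrary matrix-element groupings cannot form valid sub-matrices"
            )
        table = out.metadata(item.context)
        if isinstance(item.expr, Sym) and item.name is None:
            var = item.expr.name
            if var not in table.columns:
                raise UnresolvedSymbolError(
                    f"no {item.context.value} variable named '{var}'"
                )
        else:  # expression keys materialize as metadata first
            counter += 1
            var = item.name or f"group_{counter}"
            out = _mutate(out, [Item(item.context, var, item.expr)], env)
            table = out.metadata(item.context)
        axis_vars[item.context].append(var)
    if axis_vars[Context.ROWS]:
        out.row_grouping = GroupingSpec.from_metadata(out.row_data, axis_vars[Context.ROWS], "rows")
    if axis_vars[Context.COLS]:
        out.col_grouping = GroupingSpec.from_metadata(out.col_data, axis_vars[Context.COLS], "cols")
    return validate(out)


def _ungroup(obj: AnnotatedMatrix, axes: set[str] | None = None) -> AnnotatedMatrix:
    out = obj.copy()
    if axes is None or "rows" in axes:
        out.row_grouping = None
    if axes is None or "cols" in axes:
        out.col_grouping = None
    return out


def _group_meta(
    spec: GroupingSpec | None, length: int
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Blocks and surviving grouping-variable table for one axis."""
    if spec is None:
        return [np.arange(length, dtype=np.intp)], pd.DataFrame(index=pd.RangeIndex(1))
    blocks = spec.index_lists()
    data = {v: spec.key_values(v) for v in spec.variables}
    return blocks, pd.DataFrame(data, index=pd.RangeIndex(len(blocks)))


def _require_scalar(value: Any, context: Context) -> Any:
    if isinstance(value, (pd.Series, np.ndarray)) and np.ndim(value) > 0:
        raise SizeStabilityError(
            f"summarize expression must reduce each {context.value} group "
            f"block to a single value; got size {np.shape(value)}"
        )
    if np.ndim(value) != 0:
        raise SizeStabilityError(
            f"summarize expression must reduce each {context.value} group "
            f"block to a single value; got size {np.shape(value)}"
        )
    return value


def _summarize(obj: AnnotatedMatrix, items: list[Item], env=None) -> AnnotatedMatrix:
    row_blocks, row_meta = _group_meta(obj.row_grouping, obj.n)
    col_blocks, col_meta = _group_meta(obj.col_grouping, obj.p)
    n2, p2 = len(row_blocks), len(col_blocks)
    assays: dict[str, np.ndarray] = {}
    for item in items:
        name = _check_result_name(item.name, "summarize")
        if item.context is Context.ASSAYS:
            cells = [
                [
                    _require_scalar(
                        evaluate(item.expr, build_frame(obj, Context.ASSAYS, env, ri, ci)),
                        Context.ASSAYS,
                    )
                    for ci in col_blocks
                ]
                for ri in row_blocks
            ]
            assays[name] = np.array(cells).reshape((n2, p2))
        elif item.context is Context.ROWS:
            vals = [
                _require_scalar(
                    evaluate(item.expr, build_frame(obj, Context.ROWS, env, ri, None)),
                    Context.ROWS,
                )
                for ri in row_blocks
            ]
            row_meta[name] = np.array(vals)
        else:
            vals = [
                _require_scalar(
                    evaluate(item.expr, build_frame(obj, Context.COLS, env, None, ci)),
                    Context.COLS,
                )
                for ci in col_blocks
            ]
            col_meta[name] = np.array(vals)
    return validate(
        AnnotatedMatrix(
            assays=assays,
            row_data=row_meta,
            col_data=col_meta,
            shape=(n2, p2),
        )
    )


def _pull(obj: AnnotatedMatrix, name: str, context: Context | str = Context.ASSAYS) -> Any:
    context = Context(context) if not isinstance(context, Context) else context
    if context is Context.ASSAYS:
        if name not in obj.assays:
            raise UnresolvedSymbolError(f"no assay named '{name}'")
        return obj.assays[name].copy()
    table = obj.metadata(context)
    if name not in table.columns:
        raise UnresolvedSymbolError(f"no {context.value} variable named '{name}'")
    return table[name].to_numpy().copy()


# --------------------------------------------------------------------------
# Public surface
# --------------------------------------------------------------------------

def apply_verb(obj: AnnotatedMatrix, call: VerbCall, env: Mapping[str, Any] | None = None) -> AnnotatedMatrix:
    """Dispatch one :class:`VerbCall` against a container."""
    items = list(call.items)
    if call.verb == "mutate":
        return _mutate(obj, items, env)
    if call.verb == "filter":
        return _filter(obj, items, env)
    if call.verb == "select":
        return _select(obj, items)
    if call.verb == "arrange":
        return _arrange(obj, items, env)
    if call.verb == "group_by":
        return _group_by(obj, items, env)
    if call.verb == "ungroup":
        axes = {it.context.value for it in items} or None
        return _ungroup(obj, axes)
    if call.verb == "summarize":
        return _summarize(obj, items, env)
    raise TidymatError(f"unknown verb '{call.verb}'")


def mutate(obj: AnnotatedMatrix, *args: Any, env: Mapping[str, Any] | None = None, **kwargs: Any) -> AnnotatedMatrix:
    """Add or overwrite variables in any context.

    Items evaluate strictly left to right; later items see earlier
    results, including across contexts within one call.  Under grouping,
    evaluation runs per effective-partition block and results are
    stitched back in original index order.
    """
    return _mutate(obj, _coerce_items(args, kwargs), env)


def filter(obj: AnnotatedMatrix, *args: Any, env: Mapping[str, Any] | None = None) -> AnnotatedMatrix:  # noqa: A001
    """Subset rows and/or columns by metadata predicates.

    Multiple predicates in one context combine by logical AND; missing
    predicate values drop the record.
    """
    return _filter(obj, _coerce_items(args, {}), env)


def select(obj: AnnotatedMatrix, *args: Any) -> AnnotatedMatrix:
    """Keep only the named variables within each targeted context."""
    return _select(obj, _coerce_items(args, {}))


def arrange(obj: AnnotatedMatrix, *args: Any, env: Mapping[str, Any] | None = None) -> AnnotatedMatrix:
    """Stable-sort an axis by successive keys; ``desc(key)`` reverses one."""
    return _arrange(obj, _coerce_items(args, {}), env)


def group_by(obj: AnnotatedMatrix, *args: Any, env: Mapping[str, Any] | None = None, **kwargs: Any) -> AnnotatedMatrix:
    """Partition rows and/or columns by metadata variables."""
    return _group_by(obj, _coerce_items(args, kwargs), env)


def ungroup(obj: AnnotatedMatrix, axes: Iterable[str] | None = None) -> AnnotatedMatrix:
    """Clear grouping on the named axes (both when unspecified)."""
    return _ungroup(obj, set(axes) if axes is not None else None)


def summarize(obj: AnnotatedMatrix, *args: Any, env: Mapping[str, Any] | None = None, **kwargs: Any) -> AnnotatedMatrix:
    """Reduce each group block to one value per item.

    The result has one row per row group and one column per col group
    (1 when the axis is ungrouped); grouping variables become the
    surviving metadata and the output is ungrouped.
    """
    return _summarize(obj, _coerce_items(args, kwargs), env)


def pull(obj: AnnotatedMatrix, name: str, context: Context | str = Context.ASSAYS) -> Any:
    """Extract one stored value (assay matrix or metadata vector)."""
    return _pull(obj, name, context)
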