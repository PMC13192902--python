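"""Per-context expression evaluation: data masks, pronouns, reshaping.

Each of the three contexts (assays, rows, cols) evaluates expressions
against its own bindings — assay matrices, or metadata vectors.  The
other two contexts are reachable through pronouns, each offering an
``asis`` accessor (the stored value in its native shape) and a
``reshaped`` accessor (a size-stable transform for the current context):

* row vector requested from the assays context -> replicated across the
  ``p`` columns into an ``n x p`` matrix;
* col vector requested from the assays context -> replicated down the
  ``n`` rows;
* matrix requested from the rows (cols) context -> list of its ``n``
  rows (``p`` columns).

Reshaped accessors are lazy and memoized: no reshape work happens until
the value is touched, and at most once per frame.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from .core_model import (
    AnnotatedMatrix,
    Context,
    ContextError,
    SizeStabilityError,
    TidymatError,
    UnresolvedSymbolError,
)

__all__ = [
    "Expression",
    "Sym",
    "Lit",
    "CallExpr",
    "Pronoun",
    "ContextFrame",
    "broadcast_row_to_assay",
    "broadcast_col_to_assay",
    "slice_assay_to_rows",
    "slice_assay_to_cols",
    "build_frame",
    "evaluate",
    "check_size_stable",
    "register_function",
    "FUNCTIONS",
]


# --------------------------------------------------------------------------
# Expression AST
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Sym:
    name: str


@dataclasses.dataclass(frozen=True)
class Lit:
    value: Any


@dataclasses.dataclass(frozen=True)
class CallExpr:
    fn: str
    args: tuple["Expression", ...]


@dataclasses.dataclass(frozen=True)
class Pronoun:
    """Explicit cross-context reference like ``.rows$length``."""

    target: Context
    variant: str  # "asis" | "reshaped"
    name: str


Expression = Sym | Lit | CallExpr | Pronoun


# --------------------------------------------------------------------------
# Reshaping primitives
# --------------------------------------------------------------------------

def broadcast_row_to_assay(v: Any, p: int) -> np.ndarray:
    """Replicate a length-``n`` row vector across ``p`` columns.

    ``result[i, j] == v[i]`` for every column ``j``.
    """
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise SizeStabilityError(f"expected a 1-d vector, got ndim={arr.ndim}")
    return np.repeat(arr[:, None], p, axis=1) if p else np.empty((arr.shape[0], 0), dtype=arr.dtype)


def broadcast_col_to_assay(v: Any, n: int) -> np.ndarray:
    """Replicate a length-``p`` column vector down ``n`` rows.

    ``result[i, j] == v[j]`` for every row ``i``.
    """
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise SizeStabilityError(f"expected a 1-d vector, got ndim={arr.ndim}")
    return np.repeat(arr[None, :], n, axis=0) if n else np.empty((0, arr.shape[0]), dtype=arr.dtype)


def slice_assay_to_rows(M: Any, names: list[str] | None = None) -> list[np.ndarray]:
    """A matrix as an ordered list of its rows (optionally name-tagged)."""
    arr = np.asarray(M)
    out = [arr[i, :] for i in range(arr.shape[0])]
    if names is not None:
        return list(out)
    return out


def slice_assay_to_cols(M: Any, names: list[str] | None = None) -> list[np.ndarray]:
    """A matrix as an ordered list of its columns."""
    arr = np.asarray(M)
    return [arr[:, j] for j in range(arr.shape[1])]


# --------------------------------------------------------------------------
# Function whitelist
# --------------------------------------------------------------------------

def _np(x: Any) -> np.ndarray:
    return np.asarray(x)


def _promote(x: Any) -> Any:
    """Logical values are promoted to integer under arithmetic."""
    arr = np.asarray(x)
    if arr.dtype.kind == "b":
        return arr.astype(np.int64)
    return x


def _var(x: Any) -> float:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.var(arr, ddof=1))


def _sd(x: Any) -> float:
    v = _var(x)
    return float(np.sqrt(v))


def _mean(x: Any) -> float:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(np.mean(arr))


FUNCTIONS: dict[str, Callable[..., Any]] = {}


def register_function(name: str, fn: Callable[..., Any]) -> None:
    """Add or replace an entry in the expression-function whitelist."""
    FUNCTIONS[name] = fn


for _name, _fn in {
    "+": lambda a, b=None: +_promote(a) if b is None else _promote(a) + _promote(b),
    "-": lambda a, b=None: -_promote(a) if b is None else _promote(a) - _promote(b),
    "*": lambda a, b: _promote(a) * _promote(b),
    "/": lambda a, b: np.true_divide(_promote(a), _promote(b)),
    "^": lambda a, b: np.power(_promote(a), _promote(b)),
    "==": lambda a, b: _np(a) == _np(b),
    "!=": lambda a, b: _np(a) != _np(b),
    "<": lambda a, b: _np(a) < _np(b),
    "<=": lambda a, b: _np(a) <= _np(b),
    ">": lambda a, b: _np(a) > _np(b),
    ">=": lambda a, b: _np(a) >= _np(b),
    "&": lambda a, b: _np(a) & _np(b),
    "|": lambda a, b: _np(a) | _np(b),
    "!": lambda a: ~_np(a).astype(bool),
    "log": np.log,
    "log1p": np.log1p,
    "log2": np.log2,
    "log10": np.log10,
    "exp": np.exp,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "mean": _mean,
    "sum": lambda x: np.sum(_promote(x)),
    "min": lambda x: np.min(_np(x)),
    "max": lambda x: np.max(_np(x)),
    "median": lambda x: float(np.median(np.asarray(x, dtype=float))),
    "var": _var,
    "sd": _sd,
    "row_means": lambda M: np.mean(np.asarray(M, dtype=float), axis=1),
    "row_sums": lambda M: np.sum(_promote(M), axis=1),
    "col_means": lambda M: np.mean(np.asarray(M, dtype=float), axis=0),
    "col_sums": lambda M: np.sum(_promote(M), axis=0),
    "if_else": lambda c, y, n: np.where(_np(c).astype(bool), y, n),
}.items():
    register_function(_name, _fn)


#: functions evaluated with access to the frame rather than plain values
SPECIAL_FORMS = {"n", "row_number", "map_dbl", "desc"}


# --------------------------------------------------------------------------
# Context frames
# --------------------------------------------------------------------------

class ContextFrame:
    """The evaluation scope of one context, optionally group-restricted.

    Bindings are the names owned by the context (assay matrices or
    metadata vectors), sliced to the frame's ``group_view`` when one is
    set.  Pronoun access is routed through :meth:`resolve_pronoun`;
    reshape results are memoized and counted in :attr:`reshape_count`
    (observable laziness).
    """

    def __init__(
        self,
        obj: AnnotatedMatrix,
        context: Context,
        caller_fallback: Mapping[str, Any] | None = None,
        row_idx: np.ndarray | None = None,
        col_idx: np.ndarray | None = None,
    ):
        self.obj = obj
        self.context = context
        self.caller_fallback = caller_fallback or {}
        self.row_idx = np.arange(obj.n, dtype=np.intp) if row_idx is None else np.asarray(row_idx, dtype=np.intp)
        self.col_idx = np.arange(obj.p, dtype=np.intp) if col_idx is None else np.asarray(col_idx, dtype=np.intp)
        self._local_cache: dict[str, Any] = {}
        self._pronoun_cache: dict[tuple[Context, str, str], Any] = {}
        self.reshape_count = 0

    # --- sizes -----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.row_idx)

    @property
    def p(self) -> int:
        return len(self.col_idx)

    def axis_length(self) -> int:
        """Record count of this context: n*p cells, n rows, or p cols."""
        if self.context is Context.ASSAYS:
            return self.n * self.p
        return self.n if self.context is Context.ROWS else self.p

    def expected_shape(self) -> tuple[int, ...]:
        if self.context is Context.ASSAYS:
            return (self.n, self.p)
        return (self.axis_length(),)

    # --- symbol resolution -----------------------------------------------
    def has_local(self, name: str) -> bool:
        return name in self.obj.context_names(self.context)

    def _fetch_stored(self, target: Context, name: str) -> Any:
        """The stored value owned by ``target``, restricted to the view."""
        if target is Context.ASSAYS:
            if name not in self.obj.assays:
                raise UnresolvedSymbolError(f"no assay named '{name}'")
            return self.obj.assays[name][np.ix_(self.row_idx, self.col_idx)]
        table = self.obj.metadata(target)
        if name not in table.columns:
            raise UnresolvedSymbolError(f"no {target.value} variable named '{name}'")
        idx = self.row_idx if target is Context.ROWS else self.col_idx
        return table[name].to_numpy()[idx]

    def resolve_local(self, name: str) -> Any:
        if name not in self._local_cache:
            self._local_cache[name] = self._fetch_stored(self.context, name)
        return self._local_cache[name]

    def resolve(self, name: str) -> Any:
        """Mask-first resolution: context bindings shadow the caller."""
        if self.has_local(name):
            return self.resolve_local(name)
        if name in self.caller_fallback:
            return self.caller_fallback[name]
        raise UnresolvedSymbolError(
            f"symbol '{name}' not found in {self.context.value} context "
            "or calling scope"
        )

    def resolve_pronoun(self, target: Context, variant: str, name: str) -> Any:
        """Cross-context access; same-context pronouns are asis locals."""
        if target is self.context:
            return self.resolve_local(name)
        key = (target, variant, name)
        if key in self._pronoun_cache:
            return self._pronoun_cache[key]
        stored = self._fetch_stored(target, name)
        if variant == "asis":
            value = stored
        else:
            value = self._reshape(target, stored)
        self._pronoun_cache[key] = value
        return value

    def _reshape(self, target: Context, stored: Any) -> Any:
        self.reshape_count += 1
        if self.context is Context.ASSAYS:
            if target is Context.ROWS:
                return broadcast_row_to_assay(stored, self.p)
            return broadcast_col_to_assay(stored, self.n)
        if target is Context.ASSAYS:
            if self.context is Context.ROWS:
                return slice_assay_to_rows(stored)
            return slice_assay_to_cols(stored)
        raise ContextError(
            f"no size-stable reshape exists from {target.value} to "
            f"{self.context.value}; use the _asis pronoun variant"
        )


def build_frame(
    obj: AnnotatedMatrix,
    context: Context,
    caller_fallback: Mapping[str, Any] | None = None,
    row_idx: np.ndarray | None = None,
    col_idx: np.ndarray | None = None,
) -> ContextFrame:
    """Create the evaluation frame for one context of ``obj``.

    ``row_idx``/``col_idx`` restrict the frame to one group's slice.
    """
    return ContextFrame(obj, context, caller_fallback, row_idx, col_idx)


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

class Descending:
    """Marker produced by ``desc(key)``; only meaningful inside arrange."""

    def __init__(self, values: Any):
        self.values = values


def evaluate(expr: Expression, frame: ContextFrame) -> Any:
    """Evaluate an expression in a context frame.

    Symbols resolve mask-first (context bindings, then caller fallback);
    pronouns resolve explicitly in their target context.  Elementwise
    arithmetic between frame-shaped values is plain numpy arithmetic.
    """
    if isinstance(expr, Lit):
        return expr.value
    if isinstance(expr, Sym):
        return frame.resolve(expr.name)
    if isinstance(expr, Pronoun):
        return frame.resolve_pronoun(expr.target, expr.variant, expr.name)
    if isinstance(expr, CallExpr):
        if expr.fn in SPECIAL_FORMS:
            return _eval_special(expr, frame)
        if expr.fn not in FUNCTIONS:
            raise TidymatError(
                f"unknown function '{expr.fn}'; not in the registered whitelist"
            )
        args = [evaluate(a, frame) for a in expr.args]
        try:
            return FUNCTIONS[expr.fn](*args)
        except (UnresolvedSymbolError, TidymatError):
            raise
        except ValueError as exc:
            raise SizeStabilityError(
                f"shape mismatch inside call to '{expr.fn}': {exc}"
            ) from exc
    raise TypeError(f"not an expression node: {expr!r}")


def _eval_special(expr: CallExpr, frame: ContextFrame) -> Any:
    if expr.fn == "n":
        if expr.args:
            raise TidymatError("n() takes no arguments")
        return frame.axis_length()
    if expr.fn == "row_number":
        if expr.args:
            raise TidymatError("row_number() takes no arguments")
        return np.arange(1, frame.axis_length() + 1)
    if expr.fn == "desc":
        if len(expr.args) != 1:
            raise TidymatError("desc() takes exactly one argument")
        return Descending(evaluate(expr.args[0], frame))
    if expr.fn == "map_dbl":
        if len(expr.args) != 2 or not isinstance(expr.args[1], Sym):
            raise TidymatError(
                "map_dbl(x, f) requires a value and the bare name of a "
                "whitelisted function"
            )
        fname = expr.args[1].name
        if fname not in FUNCTIONS:
            raise TidymatError(f"unknown function '{fname}' in map_dbl")
        fn = FUNCTIONS[fname]
        items = evaluate(expr.args[0], frame)
        return np.array([float(fn(item)) for item in items], dtype=float)
    raise AssertionError(expr.fn)


def check_size_stable(
    value: Any,
    context: Context,
    expected: tuple[int, ...],
) -> np.ndarray:
    """Enforce the size-stability contract of a context.

    Matrices of shape ``n x p`` pass in the assays context; vectors of
    the axis length pass in the metadata contexts; scalars are recycled
    to the expected size.  Under grouping, ``expected`` is the group
    slice's size.  Any other size errors.
    """
    if isinstance(value, Descending):
        raise ContextError("desc() is only meaningful inside arrange()")
    if isinstance(value, (pd.Series,)):
        value = value.to_numpy()
    if isinstance(value, list):
        try:
            value = np.asarray(value)
        except ValueError:
            pass
    if np.ndim(value) == 0:
        return np.full(expected, value)
    arr = np.asarray(value)
    if arr.shape == tuple(expected):
        return arr
    want = "x".join(str(s) for s in expected)
    got = "x".join(str(s) for s in arr.shape)
    raise SizeStabilityError(
        f"result is not size-stable in {context.value} context: "
        f"got {got}, want {want}"
    )
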