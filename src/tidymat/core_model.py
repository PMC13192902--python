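"""Annotated matrix container and its structural invariants.

The central data structure couples one or more ``n x p`` value matrices
("assays") with a feature metadata table of ``n`` records (``row_data``)
and a sample metadata table of ``p`` records (``col_data``).  Features
live on rows and samples on columns throughout the package.  Optional
grouping state records a partition of either axis induced by metadata
variables.

All user-visible indices (long-table exports, Matrix Market files, error
messages) are 1-based; internal storage is 0-based numpy/pandas and must
never leak.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedMatrix",
    "Context",
    "GroupingSpec",
    "TidymatError",
    "ValidationError",
    "ContextError",
    "SizeStabilityError",
    "UnresolvedSymbolError",
    "dims",
    "make_annotated_matrix",
    "validate",
]


class TidymatError(Exception):
    """Base class for all errors raised by tidymat."""


class ValidationError(TidymatError):
    """A structural invariant of the container is violated."""


class ContextError(TidymatError):
    """An operation targets an evaluation context it is not defined for."""


class SizeStabilityError(TidymatError):
    """An expression result does not match its context's canonical size."""


class UnresolvedSymbolError(TidymatError):
    """A symbol could not be resolved in the searched context."""


class Context(enum.Enum):
    """The three evaluation contexts of the grammar."""

    ASSAYS = "assays"
    ROWS = "rows"
    COLS = "cols"


class _NAKey:
    """Hashable stand-in for missing values inside group keys."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NA"


NA_KEY = _NAKey()


def _hashable(value: Any) -> Any:
    """Map a metadata cell to a hashable group-key component (NA-safe)."""
    try:
        if pd.isna(value):
            return NA_KEY
    except (TypeError, ValueError):
        pass
    return value


def _unkey(value: Any) -> Any:
    return np.nan if value is NA_KEY else value


@dataclasses.dataclass(frozen=True)
class GroupingSpec:
    """A partition of one axis's indices induced by metadata variables.

    ``partition`` maps each group key (a tuple with one component per
    grouping variable; missing values are represented by a dedicated
    marker so they form their own group) to the ascending 0-based index
    array of the axis positions belonging to that group.  Key order is
    first-appearance order along the axis.
    """

    axis: str  # "rows" | "cols"
    variables: tuple[str, ...]
    partition: tuple[tuple[tuple, np.ndarray], ...]

    @classmethod
    def from_metadata(cls, table: pd.DataFrame, variables: Sequence[str], axis: str) -> "GroupingSpec":
        variables = tuple(variables)
        missing = [v for v in variables if v not in table.columns]
        if missing:
            raise ValidationError(
                f"grouping variables {missing} not found in {axis} metadata"
            )
        groups: dict[tuple, list[int]] = {}
        cols = [table[v].to_numpy() for v in variables]
        for i in range(len(table)):
            key = tuple(_hashable(c[i]) for c in cols)
            groups.setdefault(key, []).append(i)
        partition = tuple(
            (key, np.asarray(idx, dtype=np.intp)) for key, idx in groups.items()
        )
        return cls(axis=axis, variables=variables, partition=partition)

    @property
    def keys(self) -> list[tuple]:
        return [key for key, _ in self.partition]

    def key_values(self, variable: str) -> list[Any]:
        """Values of one grouping variable, one per group, NA restored."""
        j = self.variables.index(variable)
        return [_unkey(key[j]) for key, _ in self.partition]

    def index_lists(self) -> list[np.ndarray]:
        return [idx for _, idx in self.partition]


def _coerce_assay(name: str, value: Any) -> np.ndarray:
    arr = np.asarray(value)
    if arr.ndim != 2:
        raise ValidationError(f"assay '{name}' is not 2-dimensional (ndim={arr.ndim})")
    if arr.dtype == object or arr.dtype.kind not in "bifu":
        raise ValidationError(
            f"assay '{name}' has unsupported element type {arr.dtype}; "
            "only floating point, integer and logical assays are allowed"
        )
    return arr


def _coerce_table(value: Any, length: int | None, what: str) -> pd.DataFrame:
    if value is None:
        value = {}
    if isinstance(value, pd.DataFrame):
        df = value.reset_index(drop=True).copy()
    else:
        df = pd.DataFrame(dict(value))
    if length is not None and df.shape[1] == 0:
        df = pd.DataFrame(index=pd.RangeIndex(length))
    return df


@dataclasses.dataclass
class AnnotatedMatrix:
    """The annotated matrix container.

    Attributes
    ----------
    assays
        Ordered mapping of assay name to an ``n x p`` numeric or logical
        matrix.
    row_data, col_data
        Metadata tables with exactly ``n`` and ``p`` records.
    row_names, col_names
        Optional unique identifier strings per axis.
    row_grouping, col_grouping
        Optional :class:`GroupingSpec` per axis.
    shape
        The shared ``(n, p)`` shape; authoritative even with zero assays.
    """

    assays: dict[str, np.ndarray]
    row_data: pd.DataFrame
    col_data: pd.DataFrame
    shape: tuple[int, int]
    row_names: list[str] | None = None
    col_names: list[str] | None = None
    row_grouping: GroupingSpec | None = None
    col_grouping: GroupingSpec | None = None

    @property
    def n(self) -> int:
        return self.shape[0]

    @property
    def p(self) -> int:
        return self.shape[1]

    def copy(self) -> "AnnotatedMatrix":
        """A structural copy; assay arrays are copied, grouping shared."""
        return AnnotatedMatrix(
            assays={k: v.copy() for k, v in self.assays.items()},
            row_data=self.row_data.copy(),
            col_data=self.col_data.copy(),
            shape=self.shape,
            row_names=list(self.row_names) if self.row_names is not None else None,
            col_names=list(self.col_names) if self.col_names is not None else None,
            row_grouping=self.row_grouping,
            col_grouping=self.col_grouping,
        )

    def context_names(self, context: Context) -> list[str]:
        if context is Context.ASSAYS:
            return list(self.assays)
        if context is Context.ROWS:
            return list(self.row_data.columns)
        return list(self.col_data.columns)

    def metadata(self, context: Context) -> pd.DataFrame:
        if context is Context.ROWS:
            return self.row_data
        if context is Context.COLS:
            return self.col_data
        raise ContextError("assays context has no metadata table")

    def grouping(self, context: Context) -> GroupingSpec | None:
        if context is Context.ROWS:
            return self.row_grouping
        if context is Context.COLS:
            return self.col_grouping
        raise ContextError("assays context carries no grouping of its own")


def make_annotated_matrix(
    assays: Mapping[str, Any] | None = None,
    row_data: Any = None,
    col_data: Any = None,
    row_names: Iterable[str] | None = None,
    col_names: Iterable[str] | None = None,
    shape: tuple[int, int] | None = None,
) -> AnnotatedMatrix:
    """Construct and validate an :class:`AnnotatedMatrix`.

    ``shape`` is only required when it cannot be inferred from any assay
    or metadata table (e.g. a fully empty container).
    """
    assays = dict(assays or {})
    coerced = {name: _coerce_assay(name, m) for name, m in assays.items()}

    n = p = None
    if coerced:
        first = next(iter(coerced.values()))
        n, p = first.shape
    if shape is not None:
        n, p = int(shape[0]), int(shape[1])

    rdf = _coerce_table(row_data, None, "row_data")
    cdf = _coerce_table(col_data, None, "col_data")
    if n is None:
        n = len(rdf) if (rdf.shape[1] or len(rdf)) else 0
        p = len(cdf) if (cdf.shape[1] or len(cdf)) else 0
    if rdf.shape[1] == 0:
        rdf = pd.DataFrame(index=pd.RangeIndex(n))
    if cdf.shape[1] == 0:
        cdf = pd.DataFrame(index=pd.RangeIndex(p))

    obj = AnnotatedMatrix(
        assays=coerced,
        row_data=rdf,
        col_data=cdf,
        shape=(n, p),
        row_names=list(row_names) if row_names is not None else None,
        col_names=list(col_names) if col_names is not None else None,
    )
    return validate(obj)


def validate(obj: AnnotatedMatrix) -> AnnotatedMatrix:
    """Check every structural invariant; return ``obj`` unchanged if valid.

    All violations are collected and reported together, one diagnostic
    per violated invariant, each naming the offending component.
    """
    problems: list[str] = []
    n, p = obj.shape

    names = list(obj.assays)
    if len(set(names)) != len(names):
        problems.append("duplicate name in assays context")
    for name, m in obj.assays.items():
        if not name:
            problems.append("empty assay name")
        if m.shape != (n, p):
            problems.append(
                f"assay '{name}' has shape {m.shape[0]}x{m.shape[1]}, "
                f"expected {n}x{p}"
            )

    if len(obj.row_data) != n:
        problems.append(f"row_data length mismatch: {len(obj.row_data)} records, expected {n}")
    if len(obj.col_data) != p:
        problems.append(f"col_data length mismatch: {len(obj.col_data)} records, expected {p}")
    for table, ctx in ((obj.row_data, "rows"), (obj.col_data, "cols")):
        cols = list(table.columns)
        if len(set(cols)) != len(cols):
            problems.append(f"duplicate name in {ctx} context")

    for axis_names, axis in ((obj.row_names, "row"), (obj.col_names, "col")):
        if axis_names is not None:
            expected = n if axis == "row" else p
            if len(axis_names) != expected:
                problems.append(
                    f"{axis}_names has {len(axis_names)} entries, expected {expected}"
                )
            elif len(set(axis_names)) != len(axis_names):
                problems.append(f"{axis}_names are not unique")

    for spec, table, axis in (
        (obj.row_grouping, obj.row_data, "rows"),
        (obj.col_grouping, obj.col_data, "cols"),
    ):
        if spec is None:
            continue
        axis_len = n if axis == "rows" else p
        for v in spec.variables:
            if v not in table.columns:
                problems.append(f"grouping variable '{v}' missing from {axis} metadata")
        seen = np.concatenate([idx for _, idx in spec.partition]) if spec.partition else np.array([], dtype=np.intp)
        if len(seen) != axis_len or (len(seen) and (np.sort(seen) != np.arange(axis_len)).any()):
            problems.append(f"{axis} grouping does not partition the axis")

    if problems:
        raise ValidationError("; ".join(problems))
    return obj


def dims(obj: AnnotatedMatrix) -> tuple[int, int]:
    """The shared ``(n, p)`` shape of the container."""
    return obj.shape
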