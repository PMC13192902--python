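"""On-disk bundles, the seeded fixture generator, and interop export.

A bundle is a directory with a JSON manifest, one Matrix Market (or
dense CSV) file per assay, and TSV metadata tables.  Everything is plain
text; integers and strings round-trip bit-exactly and floats to full
precision (including NaN and infinities).
"""

from __future__ import annotations

import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core_model import AnnotatedMatrix, TidymatError, make_annotated_matrix

__all__ = [
    "BUNDLE_VERSION",
    "write_bundle",
    "read_bundle",
    "generate_fixture",
    "export_interop",
    "import_interop",
]

BUNDLE_VERSION = "1"
MANIFEST_NAME = "manifest.json"

#: missing marker used in all TSV metadata tables
NA_MARKER = "NA"

_NAME_COLUMN = ".name"  # leading dot cannot collide with user variables


def _dtype_tag(dtype: np.dtype) -> str:
    if dtype.kind == "b":
        return "logical"
    if dtype.kind in "iu":
        return "integer"
    if dtype.kind == "f":
        return "float"
    if dtype.kind in "OU":
        return "string"
    raise TidymatError(f"unserializable column type {dtype}")


def _write_assay(M: np.ndarray, path: pathlib.Path, fmt: str) -> None:
    if fmt == "mtx":
        out = M.astype(np.int64) if M.dtype.kind == "b" else M
        scipy.io.mmwrite(str(path), np.asarray(out))
    elif fmt == "csv":
        np.savetxt(path, M.reshape(M.shape[0], -1), delimiter=",", fmt="%r")
    else:  # pragma: no cover - guarded by manifest schema
        raise TidymatError(f"unknown assay format '{fmt}'")


def _read_assay(path: pathlib.Path, fmt: str, dtype_tag: str, shape: tuple[int, int]) -> np.ndarray:
    if not path.exists():
        raise TidymatError(f"missing bundle file: {path.name}")
    if fmt == "mtx":
        try:
            M = scipy.io.mmread(str(path))
        except ValueError as exc:
            raise TidymatError(f"malformed Matrix Market file {path.name}: {exc}") from exc
        if scipy.sparse.issparse(M):
            M = M.toarray()
        M = np.asarray(M)
    else:
        M = np.loadtxt(path, delimiter=",", ndmin=2)
    if M.size == 0:
        M = M.reshape(shape)
    if M.shape != shape:
        raise TidymatError(
            f"assay file {path.name} has shape {M.shape}, manifest says {shape}"
        )
    if dtype_tag == "logical":
        return M.astype(bool)
    if dtype_tag == "integer":
        return M.astype(np.int64)
    return M.astype(float)


def _write_metadata(
    table: pd.DataFrame, names: list[str] | None, path: pathlib.Path
) -> list[dict[str, str]]:
    out = pd.DataFrame(index=table.index)
    if names is not None:
        out[_NAME_COLUMN] = names
    schema = []
    for col in table.columns:
        out[col] = table[col]
        schema.append({"name": str(col), "dtype": _dtype_tag(table[col].dtype)})
    out.to_csv(path, sep="\t", na_rep=NA_MARKER, index=False)
    return schema


def _read_metadata(
    path: pathlib.Path, schema: list[dict[str, str]], length: int, named: bool, what: str
) -> tuple[pd.DataFrame, list[str] | None]:
    if not path.exists():
        raise TidymatError(f"missing bundle file: {path.name}")
    try:
        df = pd.read_csv(
            path, sep="\t", na_values=[NA_MARKER], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(index=pd.RangeIndex(0))
    if not schema and not named:
        # a zero-width unnamed table carries no records; trust the manifest
        return pd.DataFrame(index=pd.RangeIndex(length)), None
    if len(df) != length:
        raise TidymatError(
            f"{what} has {len(df)} records, manifest says {length}"
        )
    names = None
    if named:
        names = [] if length == 0 else [str(x) for x in df[_NAME_COLUMN]]
    table = pd.DataFrame(index=pd.RangeIndex(length))
    for spec in schema:
        col, tag = spec["name"], spec["dtype"]
        if length == 0:
            series = pd.Series([], dtype=object)
        else:
            series = df[col]
        if tag == "integer":
            table[col] = series.to_numpy().astype(np.int64) if length else np.array([], dtype=np.int64)
        elif tag == "float":
            table[col] = series.to_numpy().astype(float) if length else np.array([], dtype=float)
        elif tag == "logical":
            values = series.astype(str).str.lower().isin(["true", "1"]) if length else series
            table[col] = values.to_numpy().astype(bool) if length else np.array([], dtype=bool)
        else:
            table[col] = series.astype(object).to_numpy() if length else np.array([], dtype=object)
    return table, names


def write_bundle(obj: AnnotatedMatrix, path: Any) -> dict:
    """Serialize a container to a bundle directory; returns the manifest."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": BUNDLE_VERSION,
        "shape": [obj.n, obj.p],
        "assays": [],
        "row_data_file": "row_data.tsv",
        "col_data_file": "col_data.tsv",
        "row_names_present": obj.row_names is not None,
        "col_names_present": obj.col_names is not None,
    }
    for i, (name, M) in enumerate(obj.assays.items()):
        fname = f"assay_{i}.mtx"
        _write_assay(M, path / fname, "mtx")
        manifest["assays"].append(
            {"name": name, "file": fname, "format": "mtx", "dtype": _dtype_tag(M.dtype)}
        )
    manifest["row_schema"] = _write_metadata(obj.row_data, obj.row_names, path / "row_data.tsv")
    manifest["col_schema"] = _write_metadata(obj.col_data, obj.col_names, path / "col_data.tsv")
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return manifest


def read_bundle(path: Any) -> AnnotatedMatrix:
    """Read a bundle directory back into a validated container."""
    path = pathlib.Path(path)
    mpath = path / MANIFEST_NAME
    if not mpath.exists():
        raise TidymatError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(mpath.read_text())
    if "version" not in manifest:
        raise TidymatError("manifest missing mandatory 'version' field")
    n, p = (int(x) for x in manifest["shape"])
    assays = {
        spec["name"]: _read_assay(path / spec["file"], spec["format"], spec["dtype"], (n, p))
        for spec in manifest["assays"]
    }
    row_data, row_names = _read_metadata(
        path / manifest["row_data_file"], manifest["row_schema"], n,
        manifest["row_names_present"], "row_data",
    )
    col_data, col_names = _read_metadata(
        path / manifest["col_data_file"], manifest["col_schema"], p,
        manifest["col_names_present"], "col_data",
    )
    return make_annotated_matrix(
        assays=assays, row_data=row_data, col_data=col_data,
        row_names=row_names, col_names=col_names, shape=(n, p),
    )


def generate_fixture(
    n: int,
    p: int,
    n_assays: int = 1,
    n_row_vars: int = 2,
    n_col_vars: int = 2,
    seed: int = 0,
    na_rate: float = 0.0,
    with_names: bool = True,
) -> AnnotatedMatrix:
    """Deterministic synthetic container (NumPy PCG64 generator).

    Assay 1 is ``counts`` (overdispersed non-negative integers, a
    gamma-Poisson mixture); further assays are positive floats.  Row
    metadata starts with ``length`` (positive integers) and the
    categorical ``chr``; column metadata with positive ``lib_size`` and
    ``condition`` cycling over ``trt``/``untrt``.  Additional requested
    variables alternate numeric and categorical.  ``na_rate`` sprinkles
    missing values into the non-leading metadata variables.
    """
    rng = np.random.default_rng(seed)
    assays: dict[str, np.ndarray] = {}
    for a in range(n_assays):
        if a == 0:
            lam = rng.gamma(shape=2.0, scale=5.0, size=(n, p))
            assays["counts"] = rng.poisson(lam).astype(np.int64)
        else:
            name = "tpm" if a == 1 else f"assay{a + 1}"
            assays[name] = rng.gamma(shape=2.0, scale=3.0, size=(n, p)) + 0.01

    def sprinkle(values: np.ndarray) -> np.ndarray:
        if na_rate <= 0 or len(values) == 0:
            return values
        mask = rng.random(len(values)) < na_rate
        if values.dtype.kind == "f":
            values = values.copy()
            values[mask] = np.nan
        else:
            values = values.astype(object)
            values[mask] = np.nan
        return values

    row_data: dict[str, np.ndarray] = {}
    for k in range(n_row_vars):
        if k == 0:
            row_data["length"] = rng.integers(200, 10_000, size=n)
        elif k == 1:
            row_data["chr"] = np.asarray(
                [f"chr{c}" for c in rng.integers(1, 4, size=n)], dtype=object
            )
        elif k % 2 == 0:
            row_data[f"rscore{k}"] = sprinkle(rng.normal(0.0, 2.0, size=n))
        else:
            row_data[f"rclass{k}"] = sprinkle(
                np.asarray([f"r{c}" for c in rng.integers(0, 3, size=n)], dtype=object)
            )

    col_data: dict[str, np.ndarray] = {}
    for k in range(n_col_vars):
        if k == 0:
            col_data["lib_size"] = rng.integers(10_000, 1_000_000, size=p).astype(float)
        elif k == 1:
            col_data["condition"] = np.asarray(
                ["trt" if j % 2 == 0 else "untrt" for j in range(p)], dtype=object
            )
        elif k % 2 == 0:
            col_data[f"cscore{k}"] = sprinkle(rng.normal(0.0, 1.0, size=p))
        else:
            col_data[f"cclass{k}"] = sprinkle(
                np.asarray([f"c{c}" for c in rng.integers(0, 2, size=p)], dtype=object)
            )

    return make_annotated_matrix(
        assays=assays,
        row_data=pd.DataFrame(row_data, index=pd.RangeIndex(n)),
        col_data=pd.DataFrame(col_data, index=pd.RangeIndex(p)),
        row_names=[f"gene_{i + 1}" for i in range(n)] if with_names else None,
        col_names=[f"sample_{j + 1}" for j in range(p)] if with_names else None,
        shape=(n, p),
    )


def export_interop(obj: AnnotatedMatrix, path: Any) -> None:
    """Write the container as an observations-on-rows AnnData HDF5 file.

    Features-on-rows here becomes variables in the target convention,
    so every matrix is transposed on the way out; the first assay is the
    main matrix and the rest become named layers.
    """
    import anndata

    if not obj.assays:
        raise TidymatError("interop export requires at least one assay")
    names = list(obj.assays)
    var = obj.row_data.copy()
    obs = obj.col_data.copy()
    if obj.row_names is not None:
        var.index = pd.Index(obj.row_names)
    else:
        var.index = var.index.astype(str)
    if obj.col_names is not None:
        obs.index = pd.Index(obj.col_names)
    else:
        obs.index = obs.index.astype(str)
    adata = anndata.AnnData(
        X=np.asarray(obj.assays[names[0]], dtype=float).T,
        obs=obs,
        var=var,
        layers={name: np.asarray(obj.assays[name], dtype=float).T for name in names[1:]},
    )
    adata.write_h5ad(path)


def import_interop(path: Any, first_assay: str = "counts") -> AnnotatedMatrix:
    """Read an AnnData HDF5 file back (transposing to features-on-rows)."""
    import anndata

    adata = anndata.read_h5ad(path)
    X = adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    assays = {first_assay: np.asarray(X).T}
    for name in adata.layers.keys():
        layer = adata.layers[name]
        if scipy.sparse.issparse(layer):
            layer = layer.toarray()
        assays[name] = np.asarray(layer).T
    return make_annotated_matrix(
        assays=assays,
        row_data=adata.var.reset_index(drop=True),
        col_data=adata.obs.reset_index(drop=True),
        row_names=list(adata.var_names),
        col_names=list(adata.obs_names),
        shape=(adata.n_vars, adata.n_obs),
    )
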