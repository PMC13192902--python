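# tidymat

Tidy verbs for **annotated matrix data**: one or more `n x p` assay matrices
coupled to a feature (row) metadata table and a sample (column) metadata
table, manipulated through a small grammar of context-scoped expressions.

Three evaluation contexts exist:

* **assays** — the matrices (default context for bare expressions),
* **rows** — feature metadata vectors of length `n`,
* **cols** — sample metadata vectors of length `p`.

Sentinel wrappers `rows(...)` / `cols(...)` redirect expressions to a
metadata context and determine where results are stored.  The contexts are
connected by **pronouns**: `.rows$x`, `.cols$x`, `.assays$x` return a
size-stable *reshaped* view (row/col vectors broadcast to `n x p` in the
assays context; matrices sliced to lists of rows/columns in the metadata
contexts), while `.rows_asis$x` etc. return the stored value in its native
shape.  Grouping is restricted to partitions of rows or columns: the assays
context observes both axes' partitions (cross-product blocks); each
metadata context only its own axis.

A deliberately slow long-form ("unwound") implementation ships alongside as
a correctness oracle: `unwind` flattens the container to one record per
assay cell, tidy data-frame semantics apply the same verbs, and `rewind`
reconstructs the container.  The randomized equivalence of the two paths is
the package's main acceptance property.

## Library quick tour

```python
import tidymat as tm

obj = tm.generate_fixture(n=100, p=8, n_assays=2, seed=1)

out = tm.mutate(obj, "logcounts = log1p(counts)",
                     "cols(deep = lib_size > 100000)")
out = tm.filter(out, 'rows(length < 5000), cols(condition == "trt")')
out = tm.mutate(out, "norm = counts / .cols$lib_size",
                     "scaled = counts / .rows$length")
out = tm.group_by(out, "cols(condition)")
res = tm.summarize(out, "total = sum(counts)")

# two equivalent row-means routes: native-shape vs reshaped list-of-rows
out = tm.mutate(obj, "rows(ave = row_means(.assays_asis$counts), "
                     "ave2 = map_dbl(.assays$counts, mean))")

# the long-form oracle
tbl = tm.unwind(obj)          # one record per assay cell, column-major
back = tm.rewind(tbl)         # identity on data fields
```

Expressions use a whitelisted function set (arithmetic, comparisons,
boolean ops, `log`, `log1p`, `exp`, `sqrt`, `abs`, `mean`, `sum`, `min`,
`max`, `median`, `var`, `sd`, `row_means`, `col_means`, `row_sums`,
`col_sums`, `n()`, `row_number()`, `if_else`, `map_dbl`, `desc`),
extensible via `tm.register_function`.

## CLI

Bundles are plain-text directories: a JSON manifest, Matrix Market files
per assay, and TSV metadata tables (`NA` missing marker).

```sh
tidymat fixture --n 100 --p 8 --seed 1 --out demo_in
tidymat run 'mutate(logcounts = log1p(counts)) |> filter(rows(length < 5000))' \
        --in demo_in --out demo_out --long-table demo.tsv
tidymat unwind --in demo_out --out demo_long.tsv
```

`run` accepts a literal pipeline or a script file; steps chain with `|>`.
`--dry-run` validates and prints the plan; `--config cfg.yaml` can supply
any flag (flags override).  Logs go to stderr.

## Conventions

* Features on rows, samples on columns, everywhere.
* User-visible indices (long tables, Matrix Market, messages) are 1-based.
* Assay element types: float, integer, logical (promoted to integer under
  arithmetic).  Zero-length axes are legal everywhere.
* Fixture randomness uses NumPy's seeded PCG64 generator; identical
  arguments and seed reproduce containers exactly.
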