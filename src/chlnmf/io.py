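"""Expression-matrix container and plain-text readers/writers.

The in-memory container is a genes x cells dense matrix with unique string
identifiers on both axes.  On disk, dense matrices travel as TSV/CSV with a
header row of cell ids and a first column of gene ids; sparse matrices travel
as MatrixMarket coordinate files with companion ``<path>.genes`` /
``<path>.cells`` id files (one id per line).  Readers validate and reject —
they never coerce — and every rejection message carries the offending
coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
]


@dataclass
class ExpressionMatrix:
    """A non-negative genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array; must be finite and non-negative.
    gene_ids, cell_ids
        Unique string identifiers matching the two axes.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"expression matrix must be 2-D, got shape {self.values.shape}"
            )
        m, n = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{i}" for i in range(m)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{j}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != m:
            raise InvalidInputError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise InvalidInputError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise InvalidInputError(f"duplicate {name} id {dup!r}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvalidInputError(
                f"non-finite entry at gene {self.gene_ids[i]!r} (row {i}), "
                f"cell {self.cell_ids[j]!r} (column {j})"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise InvalidInputError(
                f"negative entry {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r} (row {i}), cell {self.cell_ids[j]!r} "
                f"(column {j})"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt", ".tab"):
        return "tsv"
    if ext == ".csv":
        return "csv"
    if ext == ".mtx":
        return "mtx"
    raise InvalidParameterError(
        f"cannot infer format from {path!r}; pass format='tsv'|'csv'|'mtx'"
    )


def read_expression(
    path: str,
    format: str = "auto",
    cells_in_rows: bool = False,
    log1p: bool = False,
    gene_filter_min_cells: int = 0,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket.

    ``cells_in_rows`` transposes a cells x genes table into the internal
    genes x cells orientation.  ``log1p`` applies ``log(1 + x)`` after
    reading; ``gene_filter_min_cells`` drops genes expressed (> 0) in fewer
    than that many cells.  Both preprocessing switches default to off.
    """
    if not os.path.exists(path):
        raise InvalidInputError(f"no such file: {path!r}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise InvalidInputError(f"malformed {fmt} file {path!r}: {exc}") from exc
        values = df.to_numpy()
        if values.dtype == object:
            bad = df.map(lambda v: not isinstance(v, (int, float)))
            i, j = np.argwhere(bad.to_numpy())[0]
            raise InvalidInputError(
                f"non-numeric entry at row {df.index[i]!r}, column "
                f"{df.columns[j]!r} in {path!r}"
            )
        row_ids = [str(r) for r in df.index]
        col_ids = [str(c) for c in df.columns]
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_path, col_path = path + ".genes", path + ".cells"
        if cells_in_rows:
            row_path, col_path = path + ".cells", path + ".genes"
        for p in (row_path, col_path):
            if not os.path.exists(p):
                raise InvalidInputError(
                    f"MatrixMarket companion id file missing: {p!r}"
                )
        row_ids = [line.strip() for line in open(row_path) if line.strip()]
        col_ids = [line.strip() for line in open(col_path) if line.strip()]
    else:
        raise InvalidParameterError(f"unknown format {fmt!r}")
    if cells_in_rows:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    X = ExpressionMatrix(values, gene_ids=row_ids, cell_ids=col_ids)
    if log1p:
        X = ExpressionMatrix(np.log1p(X.values), X.gene_ids, X.cell_ids)
    if gene_filter_min_cells > 0:
        keep = (X.values > 0).sum(axis=1) >= gene_filter_min_cells
        X = ExpressionMatrix(
            X.values[keep],
            [g for g, k in zip(X.gene_ids, keep) if k],
            X.cell_ids,
        )
    return X


def write_expression(X: ExpressionMatrix, path: str, format: str = "auto") -> None:
    """Write an expression matrix as TSV, CSV, or MatrixMarket + id files."""
    fmt = _detect_format(path) if format == "auto" else format
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids)
        df.to_csv(path, sep=sep)
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X.values))
        with open(path + ".genes", "w") as fh:
            fh.write("\n".join(X.gene_ids) + "\n")
        with open(path + ".cells", "w") as fh:
            fh.write("\n".join(X.cell_ids) + "\n")
    else:
        raise InvalidParameterError(f"unknown format {fmt!r}")


def read_labels(path: str) -> tuple[list[str], np.ndarray]:
    """Read a two-column TSV ``cell_id<TAB>label`` (with header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InvalidInputError(f"label file {path!r} needs two columns")
    cells = [str(c) for c in df.iloc[:, 0]]
    labels = df.iloc[:, 1].to_numpy()
    # map arbitrary label values onto 0..K-1 preserving first-appearance order
    _, codes = np.unique(labels, return_inverse=True)
    return cells, codes.astype(int)


def write_labels(cell_ids: list[str], labels: np.ndarray, path: str) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )
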