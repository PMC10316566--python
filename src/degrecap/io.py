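"""Count-matrix data model and readers/writers for the standard on-disk formats.

The pipeline exchanges three plain-text formats: 10x-style MatrixMarket
triplets (matrix.mtx + features + barcodes) for single-cell libraries,
gene-by-sample TSV tables for bulk counts, and TSV for gene lengths.  The
in-memory model is always genes x columns regardless of on-disk orientation
(10x convention stores features as rows, which happens to coincide).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


def _as_str_array(x: Iterable) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass
class CountMatrix:
    """Integer counts, genes x columns, with per-column group and library labels.

    Parameters
    ----------
    genes
        Unique gene identifiers, one per row.
    columns
        Unique column identifiers (cell barcodes or bulk sample names).
    counts
        Non-negative integer matrix, shape ``(len(genes), len(columns))``.
        Dense ndarray or any scipy sparse matrix; stored as CSC for fast
        column slicing.
    column_groups
        One label per column (cell type / condition).
    column_library
        One label per column (replicate library of origin).
    """

    genes: np.ndarray
    columns: np.ndarray
    counts: sp.spmatrix | np.ndarray
    column_groups: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_library: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = _as_str_array(self.genes)
        self.columns = _as_str_array(self.columns)
        if self.column_groups is None:
            self.column_groups = np.full(len(self.columns), "all", dtype=object)
        else:
            self.column_groups = _as_str_array(self.column_groups)
        if self.column_library is None:
            self.column_library = np.full(len(self.columns), "lib0", dtype=object)
        else:
            self.column_library = _as_str_array(self.column_library)
        if sp.issparse(self.counts):
            self.counts = sp.csc_matrix(self.counts)
        else:
            self.counts = np.asarray(self.counts)
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cols = self.counts.shape
        if len(self.genes) != n_genes:
            raise FormatError(
                f"{len(self.genes)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.columns) != n_cols:
            raise FormatError(
                f"{len(self.columns)} column ids for a matrix with {n_cols} columns"
            )
        for name, labels in (
            ("column_groups", self.column_groups),
            ("column_library", self.column_library),
        ):
            if len(labels) != n_cols:
                raise FormatError(f"{name} must have exactly one label per column")
        if len(set(self.genes)) != n_genes:
            raise FormatError("gene identifiers must be unique")
        if len(set(self.columns)) != n_cols:
            raise FormatError("column identifiers must be unique")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if np.asarray(data).size:
            arr = np.asarray(data)
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise FormatError("counts must be integers")
            if arr.size and arr.min() < 0:
                raise FormatError("counts must be non-negative")

    # -- basic views ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense integer ndarray."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return self.counts

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected_per_column(self) -> np.ndarray:
        """Number of genes with count > 0, per column."""
        if sp.issparse(self.counts):
            m = self.counts.copy()
            m.eliminate_zeros()
            return np.asarray((m > 0).sum(axis=0)).ravel()
        return (self.counts > 0).sum(axis=0)

    def select_columns(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            genes=self.genes.copy(),
            columns=self.columns[idx],
            counts=self.counts[:, idx],
            column_groups=self.column_groups[idx],
            column_library=self.column_library[idx],
        )

    def select_genes(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            genes=self.genes[idx],
            columns=self.columns.copy(),
            counts=self.counts[idx, :],
            column_groups=self.column_groups.copy(),
            column_library=self.column_library.copy(),
        )

    def with_labels(
        self,
        column_groups: Iterable | None = None,
        column_library: Iterable | None = None,
    ) -> "CountMatrix":
        cm = replace(self)
        if column_groups is not None:
            cm.column_groups = _as_str_array(column_groups)
        if column_library is not None:
            cm.column_library = _as_str_array(column_library)
        cm._validate()
        return cm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.genes, columns=self.columns)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            np.array_equal(self.genes, other.genes)
            and np.array_equal(self.columns, other.columns)
            and np.array_equal(self.column_groups, other.column_groups)
            and np.array_equal(self.column_library, other.column_library)
            and np.array_equal(self.dense(), other.dense())
        )

    @staticmethod
    def concat_columns(parts: Sequence["CountMatrix"]) -> "CountMatrix":
        """Stack matrices sharing the same gene axis side by side."""
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.genes, first.genes):
                raise FormatError("cannot concatenate matrices with different genes")
        mats = [
            p.counts if sp.issparse(p.counts) else sp.csc_matrix(p.counts)
            for p in parts
        ]
        return CountMatrix(
            genes=first.genes.copy(),
            columns=np.concatenate([p.columns for p in parts]),
            counts=sp.hstack(mats, format="csc"),
            column_groups=np.concatenate([p.column_groups for p in parts]),
            column_library=np.concatenate([p.column_library for p in parts]),
        )


GeneLengths = Mapping[str, int]
"""gene_id -> transcript/gene length in bases (positive integers)."""


def validate_gene_lengths(lengths: GeneLengths, genes: Iterable[str]) -> None:
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise FormatError(f"gene lengths missing for {len(missing)} genes, e.g. {missing[:3]}")
    bad = [g for g, L in lengths.items() if L < 1]
    if bad:
        raise FormatError(f"gene lengths must be >= 1; offending ids e.g. {bad[:3]}")


# -- 10x-style MTX triplet ---------------------------------------------------


def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path: Path | str) -> list[str]:
    with _open_text(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _make_unique(ids: list[str]) -> list[str]:
    """Disambiguate duplicate ids by appending '.1', '.2', ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def read_10x_mtx(
    matrix_path: Path | str,
    features_path: Path | str,
    barcodes_path: Path | str,
) -> CountMatrix:
    """Read a Cell Ranger-style triplet into a genes x cells CountMatrix.

    Features are rows on disk (the 10x convention).  Duplicate feature ids are
    made unique with a ``.1``, ``.2`` suffix on repeats.  A feature line may
    carry tab-separated extra fields (gene symbol, feature type); only the
    first field is used as the identifier.
    """
    try:
        with _open_text(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # mmread raises bare ValueError on garbage
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer entries in {matrix_path}")
    if mat.data.size and mat.data.min() < 0:
        raise FormatError(f"negative entries in {matrix_path}")
    features = [ln.split("\t")[0] for ln in _read_lines(features_path)]
    barcodes = _read_lines(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but triplet has {len(features)} features "
            f"and {len(barcodes)} barcodes"
        )
    return CountMatrix(
        genes=_make_unique(features),
        columns=barcodes,
        counts=mat.astype(np.int64),
    )


def write_10x_mtx(
    cm: CountMatrix,
    matrix_path: Path | str,
    features_path: Path | str,
    barcodes_path: Path | str,
) -> None:
    """Write a CountMatrix as a 10x-style triplet (features as matrix rows)."""
    mat = cm.counts if sp.issparse(cm.counts) else sp.csc_matrix(cm.counts)
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(mat.astype(np.int64)))
    # mmwrite appends .mtx if absent; normalize so the triplet stays findable
    written = Path(str(matrix_path))
    if not written.exists() and written.with_suffix(written.suffix + ".mtx").exists():
        written.with_suffix(written.suffix + ".mtx").rename(written)
    with _open_text(features_path, "wt") as fh:
        for g in cm.genes:
            fh.write(f"{g}\n")
    with _open_text(barcodes_path, "wt") as fh:
        for b in cm.columns:
            fh.write(f"{b}\n")


# -- TSV count tables --------------------------------------------------------


def read_counts_tsv(path: Path | str) -> CountMatrix:
    """Read a gene x sample TSV of integer counts (header = sample names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.size:
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path}")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"fractional counts in {path}")
        if arr.min() < 0:
            raise FormatError(f"negative counts in {path}")
    return CountMatrix(
        genes=df.index.astype(str).tolist(),
        columns=df.columns.astype(str).tolist(),
        counts=arr.astype(np.int64),
    )


def write_counts_tsv(cm: CountMatrix, path: Path | str) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths_tsv(path: Path | str) -> dict[str, int]:
    """Two-column TSV: gene_id, length in bases."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"gene-length table {path} needs two columns")
    ids = df.iloc[:, 0].astype(str)
    lengths = df.iloc[:, 1].astype(int)
    if (lengths < 1).any():
        raise FormatError("gene lengths must be >= 1")
    return dict(zip(ids, lengths))


def write_gene_lengths_tsv(lengths: GeneLengths, path: Path | str) -> None:
    pd.DataFrame(
        {"gene_id": list(lengths.keys()), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def match_genes(a: CountMatrix, b: CountMatrix) -> tuple[CountMatrix, CountMatrix, int]:
    """Restrict two matrices to their shared genes (exact id match, a's order).

    Returns the two restricted matrices and the number of genes dropped from
    either side; callers should report that count rather than hiding it.
    """
    shared = [g for g in a.genes if g in set(b.genes)]
    dropped = (a.n_genes - len(shared)) + (b.n_genes - len(shared))
    a_idx = {g: i for i, g in enumerate(a.genes)}
    b_idx = {g: i for i, g in enumerate(b.genes)}
    a2 = a.select_genes(np.array([a_idx[g] for g in shared], dtype=int))
    b2 = b.select_genes(np.array([b_idx[g] for g in shared], dtype=int))
    return a2, b2, dropped
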