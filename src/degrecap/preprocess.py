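"""Cell filtering, pseudo-bulk aggregation, TPM, and single-cell log-normalization.

These four steps are the fixed preprocessing vocabulary of the pipeline:
cells are kept when their number of detected genes lies in an inclusive
window (default 200-5,000); pseudo-bulk samples are plain per-gene sums of
counts over the cells of a group; abundance is quantified as transcripts per
million using a gene-length table; and single cells are depth-normalized to a
fixed scale factor (default 10,000) and log1p-transformed, the LogNormalize
convention (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, GeneLengths, validate_gene_lengths


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class CellFilterParams:
    """Inclusive bounds on the number of detected (count > 0) genes per cell."""

    min_genes_detected: int = 200
    max_genes_detected: int = 5000

    def __post_init__(self) -> None:
        if not (0 <= self.min_genes_detected < self.max_genes_detected):
            raise ValueError("need 0 <= min_genes_detected < max_genes_detected")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression; same axes as the CountMatrix it came from."""

    genes: np.ndarray
    columns: np.ndarray
    values: sp.spmatrix | np.ndarray
    column_groups: np.ndarray
    column_library: np.ndarray

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values


def filter_cells(cm: CountMatrix, params: CellFilterParams = CellFilterParams()) -> CountMatrix:
    """Keep cells whose detected-gene count lies within the inclusive bounds."""
    if cm.n_columns < 1:
        raise PreprocessError("empty matrix")
    detected = cm.genes_detected_per_column()
    keep = (detected >= params.min_genes_detected) & (detected <= params.max_genes_detected)
    if not keep.any():
        raise PreprocessError(
            f"all {cm.n_columns} cells removed by filter "
            f"[{params.min_genes_detected}, {params.max_genes_detected}]"
        )
    return cm.select_columns(np.flatnonzero(keep))


def pseudo_bulk(cm: CountMatrix, group_by: np.ndarray | None = None) -> CountMatrix:
    """Sum counts per gene over the cells of each group.

    ``group_by`` defaults to ``column_groups``; pass e.g.
    ``cm.column_groups + ":" + cm.column_library`` style labels to aggregate
    per (type, replicate library).  Output columns are in first-appearance
    order of the labels and keep a group/library label when it is constant
    within the aggregated cells.
    """
    labels = np.asarray(
        cm.column_groups if group_by is None else list(group_by), dtype=object
    )
    if len(labels) != cm.n_columns:
        raise PreprocessError("one group label per column required")
    uniq = list(dict.fromkeys(labels))
    cols = np.zeros((cm.n_genes, len(uniq)), dtype=np.int64)
    out_groups, out_libs = [], []
    for j, lab in enumerate(uniq):
        idx = np.flatnonzero(labels == lab)
        block = cm.counts[:, idx]
        cols[:, j] = np.asarray(block.sum(axis=1)).ravel()
        g = set(cm.column_groups[idx])
        lb = set(cm.column_library[idx])
        out_groups.append(g.pop() if len(g) == 1 else str(lab))
        out_libs.append(lb.pop() if len(lb) == 1 else str(lab))
    return CountMatrix(
        genes=cm.genes.copy(),
        columns=[str(u) for u in uniq],
        counts=cols,
        column_groups=out_groups,
        column_library=out_libs,
    )


def tpm(cm: CountMatrix, lengths: GeneLengths) -> np.ndarray:
    """Transcripts per million, per column; each column sums to 1e6.

    rate_g = count_g / length_kb_g; TPM_g = rate_g / sum(rate) * 1e6.
    """
    validate_gene_lengths(lengths, cm.genes)
    kb = np.array([lengths[g] for g in cm.genes], dtype=float) / 1000.0
    dense = cm.dense().astype(float)
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        bad = cm.columns[np.flatnonzero(totals == 0)[0]]
        raise PreprocessError(f"TPM undefined for all-zero column {bad!r}")
    rate = dense / kb[:, None]
    return rate / rate.sum(axis=0, keepdims=True) * 1e6


def log_normalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """value = ln(1 + scale_factor * count / cell_total); zeros stay zero."""
    totals = cm.column_totals().astype(float)
    if (totals == 0).any():
        bad = cm.columns[np.flatnonzero(totals == 0)[0]]
        raise PreprocessError(f"cannot normalize zero-total cell {bad!r}")
    if sp.issparse(cm.counts):
        mat = sp.csc_matrix(cm.counts, dtype=float)
        # scale the stored nonzeros column-wise, then log1p (log1p(0)=0)
        col_scale = scale_factor / totals
        mat = mat @ sp.diags(col_scale)
        mat.data = np.log1p(mat.data)
        values: sp.spmatrix | np.ndarray = mat
    else:
        values = np.log1p(cm.counts * (scale_factor / totals)[None, :])
    return NormalizedMatrix(
        genes=cm.genes.copy(),
        columns=cm.columns.copy(),
        values=values,
        column_groups=cm.column_groups.copy(),
        column_library=cm.column_library.copy(),
    )
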