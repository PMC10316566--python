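"""Cell subsampling and sequencing-depth thinning with reproducible seeds.

Two axes of data reduction are studied: random subsets of cells (stratified
by replicate library, repeated with fresh draws at each level) and reduction
of bulk sequencing depth.  Depth reduction is performed at the count level:
each column's counts are replaced by a without-replacement sample of
``target_total`` reads, i.e. a multivariate hypergeometric draw over genes —
the exact count-level image of sampling reads without replacement and
re-counting them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

DEFAULT_CELL_FRACTIONS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05, 0.02, 0.01)
DEFAULT_READ_DEPTHS = (100_000_000, 40_000_000, 20_000_000, 10_000_000, 5_000_000)


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SamplingPlan:
    """Grid of cell fractions and read depths to evaluate, with repeat count."""

    cell_fractions: tuple[float, ...] = DEFAULT_CELL_FRACTIONS
    n_repeats: int = 3
    read_depths: tuple[int, ...] = DEFAULT_READ_DEPTHS
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(self.cell_fractions)
        if any(not (0 < f <= 1) for f in fr):
            raise ValueError("cell fractions must lie in (0, 1]")
        if len(set(fr)) != len(fr) or list(fr) != sorted(fr, reverse=True):
            raise ValueError("cell fractions must be unique and sorted descending")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        object.__setattr__(self, "cell_fractions", fr)
        object.__setattr__(self, "read_depths", tuple(self.read_depths))


def derive_seed(root_seed: int, *parts) -> np.random.SeedSequence:
    """Stable stream splitting: hash each part into the spawn key.

    Adding new fractions/repeats/libraries never perturbs existing draws
    because each combination owns an independent stream.
    """
    key = [zlib.crc32(repr(p).encode()) for p in parts]
    return np.random.SeedSequence(entropy=int(root_seed) & 0x7FFFFFFF, spawn_key=tuple(key))


def subsample_cells(
    cm: CountMatrix, fraction: float, repeat_index: int = 0, seed: int = 0
) -> CountMatrix:
    """Sample round(fraction * n) cells per replicate library, no replacement.

    Fraction 1.0 returns all cells exactly once (no resampling).  Sampled
    cells keep their counts untouched; the gene set is unchanged.  Draws for
    different (fraction, repeat_index, library) combinations are independent.
    """
    if not (0 < fraction <= 1):
        raise SamplingError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return cm
    keep: list[np.ndarray] = []
    for lib in dict.fromkeys(cm.column_library):
        idx = np.flatnonzero(cm.column_library == lib)
        n_take = int(round(fraction * len(idx)))
        if n_take == 0:
            raise SamplingError(
                f"fraction {fraction} rounds to zero cells in library {lib!r}"
            )
        rng = np.random.default_rng(derive_seed(seed, float(fraction), int(repeat_index), str(lib)))
        keep.append(np.sort(rng.choice(idx, size=n_take, replace=False)))
    return cm.select_columns(np.sort(np.concatenate(keep)))


def thin_reads(cm: CountMatrix, target_total: int, seed: int = 0) -> CountMatrix:
    """Thin each column to exactly ``target_total`` reads without replacement.

    Per column the retained counts are a multivariate hypergeometric draw
    over genes, so the expected thinned count of a gene is
    target_total * count / column_total and the column total is hit exactly.
    """
    totals = cm.column_totals()
    if (target_total > totals).any():
        j = int(np.flatnonzero(target_total > totals)[0])
        raise SamplingError(
            f"target {target_total} exceeds available total {totals[j]} "
            f"in column {cm.columns[j]!r}"
        )
    dense = cm.dense().astype(np.int64)
    out = np.empty_like(dense)
    for j in range(dense.shape[1]):
        if totals[j] == target_total:
            out[:, j] = dense[:, j]
            continue
        rng = np.random.default_rng(derive_seed(seed, int(target_total), str(cm.columns[j])))
        out[:, j] = rng.multivariate_hypergeometric(
            dense[:, j], target_total, method="marginals"
        )
    counts = sp.csc_matrix(out) if sp.issparse(cm.counts) else out
    return CountMatrix(
        genes=cm.genes.copy(),
        columns=cm.columns.copy(),
        counts=counts,
        column_groups=cm.column_groups.copy(),
        column_library=cm.column_library.copy(),
    )
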