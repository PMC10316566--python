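"""Comparison statistics: DEG overlaps, stratified recapitulation, correlations.

The evaluation grid asks, for every data-reduction level, how much of a
reference DEG set (bulk replicates, NB test, BH <= 0.05) is recovered by
re-analysis of reduced data — overall, within quartiles of the reference
DEGs by p-value / |log2FC| / abundance, and within the "modest DEG" window
that mimics condition-vs-condition effect sizes — plus rank correlations of
p-values and of abundance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix
from .preprocess import CellFilterParams, filter_cells, log_normalize, pseudo_bulk, tpm
from . import de as de_mod
from .downsample import SamplingPlan, subsample_cells, thin_reads, derive_seed


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ModestDEGCriteria:
    """Inclusive windows selecting reference DEGs with modest effect sizes."""

    p_unadj_range: tuple[float, float] = (3.1e-5, 0.025)
    p_adj_range: tuple[float, float] = (1e-4, 0.05)
    abs_log2fc_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.p_unadj_range, self.p_adj_range, self.abs_log2fc_range):
            if lo > hi:
                raise ValueError("interval bounds must be ordered")


def assign_quartiles(values, gene_ids, ascending: bool = True) -> np.ndarray:
    """Quartile labels 1-4 after sorting by value (ties break by gene id).

    Q1 holds the first quarter of the sort order; with n not divisible by 4
    the leading quartiles take the extra genes.
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(gene_ids, dtype=str)
    if len(values) < 4:
        raise EvaluationError(f"need >= 4 genes to form quartiles, got {len(values)}")
    key = values if ascending else -values
    order = np.lexsort((ids, key))
    q = np.empty(len(values), dtype=int)
    for i, chunk in enumerate(np.array_split(order, 4)):
        q[chunk] = i + 1
    return q


# -- pairwise statistics -----------------------------------------------------


def detection_overlap(a: pd.Series, b: pd.Series) -> tuple[int, int, int]:
    """Venn counts of genes detected (TPM > 0) in two abundance tables."""
    a, b = a.align(b, fill_value=0.0)
    da = a > 0
    db = b > 0
    return int((da & ~db).sum()), int((db & ~da).sum()), int((da & db).sum())


def profile_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman correlation of log2(TPM+1) over the shared gene universe.

    Genes missing or undetected on one side enter as 0 TPM.
    """
    a, b = a.align(b, fill_value=0.0)
    x = np.log2(a.to_numpy() + 1.0)
    y = np.log2(b.to_numpy() + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("zero variance in an abundance profile")
    return float(scipy.stats.spearmanr(x, y).statistic)


def recapitulation(reference_degs: set, test_degs: set) -> tuple[float, int, int]:
    """(rate, n_overlap, n_unique_to_test) of a test DEG set vs the reference."""
    if not reference_degs:
        raise EvaluationError("empty reference DEG set; rate undefined")
    overlap = len(reference_degs & test_degs)
    return overlap / len(reference_degs), overlap, len(test_degs - reference_degs)


_STRATIFIERS = {
    "p": ("p_unadj", True),
    "abs_log2fc": ("log2fc", False),
    "abundance": ("mean_tpm", False),
}


def stratified_recapitulation(
    reference_de: pd.DataFrame,
    reference_degs: set,
    test_degs: set,
    stratifier: str,
) -> np.ndarray:
    """Recapitulation rate within quartiles Q1-Q4 of the reference DEGs.

    Quartile direction follows the stratifier: p ascending (Q1 = smallest),
    |log2FC| and abundance descending (Q1 = largest / most abundant).
    """
    if stratifier not in _STRATIFIERS:
        raise EvaluationError(f"unknown stratifier {stratifier!r}")
    col, ascending = _STRATIFIERS[stratifier]
    sub = reference_de[reference_de["gene_id"].isin(reference_degs)]
    vals = sub[col].to_numpy(dtype=float)
    if col == "log2fc":
        vals = np.abs(vals)
    q = assign_quartiles(vals, sub["gene_id"].to_numpy(), ascending=ascending)
    rates = np.empty(4)
    genes = sub["gene_id"].to_numpy()
    for i in range(4):
        members = set(genes[q == i + 1])
        rates[i] = len(members & test_degs) / len(members)
    return rates


def modest_deg_subset(
    reference_de: pd.DataFrame, criteria: ModestDEGCriteria = ModestDEGCriteria()
) -> set[str]:
    """Reference genes inside all three inclusive modest-effect windows."""
    p = reference_de["p_unadj"].to_numpy(dtype=float)
    padj = reference_de["p_bh"].to_numpy(dtype=float)
    lfc = np.abs(reference_de["log2fc"].to_numpy(dtype=float))
    lo, hi = criteria.p_unadj_range
    m = (p >= lo) & (p <= hi)
    lo, hi = criteria.p_adj_range
    m &= (padj >= lo) & (padj <= hi)
    lo, hi = criteria.abs_log2fc_range
    m &= (lfc >= lo) & (lfc <= hi)
    m &= ~np.isnan(p)
    return set(reference_de.loc[m, "gene_id"])


def pvalue_correlation(
    reference_de: pd.DataFrame, test_de: pd.DataFrame, gene_set: set
) -> float:
    """Spearman rho of unadjusted p-values over a fixed gene set.

    Genes absent or untested on the test side enter with p = 1 so the gene
    set — and hence the correlations across reduction levels — stays fixed.
    """
    if len(gene_set) < 3:
        raise EvaluationError("need at least 3 genes for a rank correlation")
    genes = sorted(gene_set)
    ref = reference_de.set_index("gene_id")["p_unadj"].reindex(genes)
    test = test_de.set_index("gene_id")["p_unadj"].reindex(genes).fillna(1.0)
    return float(scipy.stats.spearmanr(ref.to_numpy(), test.to_numpy()).statistic)


# -- orchestration -----------------------------------------------------------


def pseudo_bulk_by_replicate(cm: CountMatrix) -> CountMatrix:
    """One pseudo-bulk sample per (cell type, replicate library)."""
    labels = np.array(
        [f"{g}|{l}" for g, l in zip(cm.column_groups, cm.column_library)], dtype=object
    )
    return pseudo_bulk(cm, labels)


def _attach_mean_tpm(de: pd.DataFrame, tpm_mean: pd.Series) -> pd.DataFrame:
    de = de.copy()
    de["mean_tpm"] = de["gene_id"].map(tpm_mean).to_numpy()
    return de


def mean_tpm(cm: CountMatrix, lengths) -> pd.Series:
    return pd.Series(tpm(cm, lengths).mean(axis=1), index=list(cm.genes))


def _stat_row(reference_de, reference_degs, modest, test_de, test_tpm, ref_tpm, alpha, adjustment):
    test_degs = de_mod.call_degs(test_de, alpha=alpha, adjustment=adjustment)
    rate, overlap, unique = recapitulation(reference_degs, test_degs)
    row = {
        "n_degs_reference": len(reference_degs),
        "n_degs_test": len(test_degs),
        "n_overlap": overlap,
        "recapitulation_rate": rate,
        "unique_to_test": unique,
        "modest_recapitulation": (
            len(modest & test_degs) / len(modest) if modest else np.nan
        ),
        "spearman_p": pvalue_correlation(reference_de, test_de, reference_degs),
        "spearman_abundance": (
            profile_correlation(ref_tpm, test_tpm) if test_tpm is not None else np.nan
        ),
    }
    for strat, tag in (("p", "p"), ("abs_log2fc", "lfc"), ("abundance", "tpm")):
        rates = stratified_recapitulation(reference_de, reference_degs, test_degs, strat)
        for i in range(4):
            row[f"q_{tag}_{i + 1}"] = rates[i]
    return row


REPORT_COLUMNS = [
    "axis", "method", "level", "repeat", "n_cells",
    "n_degs_reference", "n_degs_test", "n_overlap", "recapitulation_rate",
    "unique_to_test", "modest_recapitulation", "spearman_p", "spearman_abundance",
    "q_p_1", "q_p_2", "q_p_3", "q_p_4",
    "q_lfc_1", "q_lfc_2", "q_lfc_3", "q_lfc_4",
    "q_tpm_1", "q_tpm_2", "q_tpm_3", "q_tpm_4",
]


def run_full_evaluation(
    experiment,
    plan: SamplingPlan,
    alpha: float = 0.05,
    cell_filter: CellFilterParams | None = CellFilterParams(),
    modest_criteria: ModestDEGCriteria = ModestDEGCriteria(),
) -> pd.DataFrame:
    """Run the full reduction grid and return one tidy row per combination.

    ``experiment`` is a SimulatedExperiment (or any object with
    ``single_cell``, ``bulk`` and ``gene_lengths`` attributes).  For every
    cell fraction x repeat, the filtered single-cell data are subsampled and
    analyzed two ways — pseudo-bulk NB test (BH) and direct Wilcoxon (BH and,
    separately, Bonferroni) — and compared against the bulk reference
    (NB test, BH <= alpha, full data).  For every read depth the bulk counts
    are thinned and re-tested against the full-depth reference.  At fraction
    1.0 the repeats are identical by construction and are reported as copies.
    """
    lengths = experiment.gene_lengths
    bulk = experiment.bulk

    ref_tpm = mean_tpm(bulk, lengths)
    reference_de = _attach_mean_tpm(de_mod.nb_wald_test(bulk), ref_tpm)
    reference_degs = de_mod.call_degs(reference_de, alpha=alpha, adjustment="bh")
    if not reference_degs:
        raise EvaluationError("bulk reference analysis found no DEGs")
    modest = modest_deg_subset(
        reference_de[reference_de["gene_id"].isin(reference_degs)], modest_criteria
    )

    sc = experiment.single_cell
    if cell_filter is not None:
        sc = filter_cells(sc, cell_filter)
    norm_full = log_normalize(sc)

    rows = []

    def eval_fraction(fraction: float, repeat: int) -> list[dict]:
        sub = subsample_cells(sc, fraction, repeat_index=repeat, seed=plan.seed)
        keep = {c: i for i, c in enumerate(sc.columns)}
        idx = np.array([keep[c] for c in sub.columns], dtype=int)
        pb = pseudo_bulk_by_replicate(sub)
        pb_de = de_mod.nb_wald_test(pb)
        pb_tpm = mean_tpm(pb, lengths)
        sub_norm = _subset_norm(norm_full, idx)
        wx_de = de_mod.wilcoxon_rank_sum(sub_norm)
        out = []
        for method, test_de, adjustment, test_tpm in (
            ("pseudobulk_bh", pb_de, "bh", pb_tpm),
            ("sc_wilcoxon_bh", wx_de, "bh", pb_tpm),
            ("sc_wilcoxon_bonf", wx_de, "bonferroni", pb_tpm),
        ):
            row = {
                "axis": "cells", "method": method,
                "level": fraction, "repeat": repeat, "n_cells": sub.n_columns,
            }
            row.update(
                _stat_row(reference_de, reference_degs, modest, test_de,
                          test_tpm, ref_tpm, alpha, adjustment)
            )
            out.append(row)
        return out

    for fraction in plan.cell_fractions:
        if fraction == 1.0:
            once = eval_fraction(1.0, 0)
            for repeat in range(plan.n_repeats):
                for row in once:
                    rows.append({**row, "repeat": repeat})
        else:
            for repeat in range(plan.n_repeats):
                rows.extend(eval_fraction(fraction, repeat))

    min_total = int(bulk.column_totals().min()) if plan.read_depths else 0
    for depth in plan.read_depths:
        if depth >= min_total:
            thinned = bulk
        else:
            thinned = thin_reads(bulk, int(depth), seed=plan.seed)
        th_de = de_mod.nb_wald_test(thinned)
        th_tpm = mean_tpm(thinned, lengths)
        row = {
            "axis": "reads", "method": "bulk_nb_bh",
            "level": float(depth), "repeat": 0, "n_cells": 0,
        }
        row.update(
            _stat_row(reference_de, reference_degs, modest, th_de,
                      th_tpm, ref_tpm, alpha, "bh")
        )
        rows.append(row)

    return pd.DataFrame(rows)[REPORT_COLUMNS]


def _subset_norm(norm, idx: np.ndarray):
    from .preprocess import NormalizedMatrix

    return NormalizedMatrix(
        genes=norm.genes,
        columns=norm.columns[idx],
        values=norm.values[:, idx],
        column_groups=norm.column_groups[idx],
        column_library=norm.column_library[idx],
    )
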