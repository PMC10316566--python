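"""Synthetic paired bulk / single-cell experiment with known ground truth.

The generator emulates a two-cell-type design in which three replicate
rounds of culture are each split into a single-cell library and a bulk
RNA-seq sample, so bulk and single-cell data of a replicate share the same
biological signal.  The hierarchy is:

* per-gene baseline expression rates are log-normal across genes;
* a chosen fraction of genes is truly differential, with log2 fold changes
  drawn from a mixture of modest (|lfc| in [0.5, 2]) and large (|lfc| > 2)
  effects, random sign;
* each (gene, replicate, type) mean is perturbed log-normally
  (``replicate_noise_sd``) — the biological between-replicate variation;
* single-cell counts are negative-binomial draws at per-cell library sizes
  (log-normal, 10x-like defaults) with a per-gene dispersion from a
  mean-dependent trend times log-normal noise; bulk counts are NB draws at
  ``bulk_depth`` around the same perturbed per-replicate proportions.

Dropout is implicit: at shallow per-cell depth most NB means are far below 1,
so zeros dominate without an explicit zero-inflation term.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .evaluate import assign_quartiles
from .de import call_degs


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-experiment generator.

    Defaults mirror the study design being emulated: two cell types, three
    replicate libraries per type, ~5,000 cells per type, three bulk
    replicates per type at 100 million counts each.  Library-size and
    dispersion defaults are typical of 10x 3' v3.1 data.
    """

    n_genes: int = 10_000
    n_cells_per_type: int = 5_000
    n_bulk_replicates: int = 3
    n_sc_libraries: int = 3
    frac_de: float = 0.3
    # true |log2FC| mixture: modest effects in [0.5, 2], large effects above 2
    modest_weight: float = 0.5
    modest_lfc_range: tuple[float, float] = (0.5, 2.0)
    large_lfc_range: tuple[float, float] = (2.0, 5.0)
    # log-scale gene baseline-rate distribution (relative; normalized away)
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 2.0
    # per-gene NB dispersion trend alpha(m) = a0 + a1/m, times exp(N(0, sd))
    disp_a0: float = 0.1
    disp_a1: float = 1.0
    disp_sdlog: float = 0.25
    bulk_dispersion: float = 0.005
    # per-cell total-count (library size) distribution, log-normal
    libsize_meanlog: float = float(np.log(8_000.0))
    libsize_sdlog: float = 0.35
    bulk_depth: int = 100_000_000
    replicate_noise_sd: float = 0.10
    gene_length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells_per_type, self.n_bulk_replicates,
               self.n_sc_libraries, self.bulk_depth) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.frac_de < 1):
            raise ValueError("frac_de must lie in [0, 1)")
        if not (0 <= self.modest_weight <= 1):
            raise ValueError("modest_weight must lie in [0, 1]")
        if min(self.disp_a0, self.bulk_dispersion) <= 0:
            raise ValueError("dispersions must be > 0")
        if self.replicate_noise_sd < 0 or self.disp_sdlog < 0:
            raise ValueError("noise sds must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedExperiment:
    """Output bundle: single-cell libraries, bulk table, truth, gene lengths."""

    single_cell_libraries: dict[str, CountMatrix]
    bulk: CountMatrix
    truth: pd.DataFrame
    gene_lengths: dict[str, int]
    config: SimulationConfig

    @property
    def single_cell(self) -> CountMatrix:
        """All libraries side by side (cells keep their library labels)."""
        return CountMatrix.concat_columns(list(self.single_cell_libraries.values()))


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB sampling; alpha broadcasts over the trailing axes of mu."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_paired_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the paired experiment; identical config + seed is bit-identical."""
    root = np.random.SeedSequence(config.seed)
    (ss_truth, ss_rep, ss_sc, ss_bulk, ss_len) = root.spawn(5)
    rng = np.random.default_rng(ss_truth)

    G = config.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(G)], dtype=object)

    # ground truth: baseline rates, DE labels, effect sizes, dispersions
    lam = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=G)
    n_de = int(round(config.frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    lfc = np.zeros(G)
    if n_de:
        is_modest = rng.random(n_de) < config.modest_weight
        mag = np.where(
            is_modest,
            rng.uniform(*config.modest_lfc_range, size=n_de),
            rng.uniform(*config.large_lfc_range, size=n_de),
        )
        sign = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = mag * sign

    lam_b = lam * 2.0**lfc
    mean_libsize = float(np.exp(config.libsize_meanlog + 0.5 * config.libsize_sdlog**2))
    base_mean = lam / lam.sum() * mean_libsize  # expected type-A count per cell
    if base_mean.max() < 1e-4:
        raise SimulationError(
            "degenerate simulation: expected per-cell counts round to all zero"
        )
    disp_trend = config.disp_a0 + config.disp_a1 / np.maximum(base_mean, 1e-6)
    dispersion = disp_trend * rng.lognormal(0.0, config.disp_sdlog, size=G)

    rng_len = np.random.default_rng(ss_len)
    lengths = rng_len.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=G
    )
    gene_lengths = dict(zip(gene_ids, (int(x) for x in lengths)))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base_mean,
            "true_log2fc": lfc,
            "dispersion": dispersion,
            "is_de": lfc != 0.0,
            "length": lengths,
        }
    )

    # per-(gene, replicate) biological perturbation, shared by the two types of
    # a replicate (each replicate round is split into both types and both
    # assays) — so with frac_de = 0 the types are exactly exchangeable
    n_rep = max(config.n_bulk_replicates, config.n_sc_libraries)
    rng_rep = np.random.default_rng(ss_rep)
    eps = rng_rep.normal(0.0, config.replicate_noise_sd, size=(n_rep, G))
    type_lams = {"typeA": lam, "typeB": lam_b}
    props: dict[tuple[str, int], np.ndarray] = {}
    for t in ("typeA", "typeB"):
        for r in range(n_rep):
            pert = type_lams[t] * np.exp(eps[r])
            props[(t, r)] = pert / pert.sum()

    # single-cell libraries
    rng_sc = np.random.default_rng(ss_sc)
    per_lib = _split_sizes(config.n_cells_per_type, config.n_sc_libraries)
    libraries: dict[str, CountMatrix] = {}
    for t in ("typeA", "typeB"):
        for r in range(config.n_sc_libraries):
            n_cells = per_lib[r]
            lib_name = f"{t}_rep{r + 1}"
            libsizes = rng_sc.lognormal(
                config.libsize_meanlog, config.libsize_sdlog, size=n_cells
            )
            p = props[(t, r)]
            blocks = []
            for start in range(0, n_cells, 512):
                stop = min(start + 512, n_cells)
                mu = np.outer(p, libsizes[start:stop])
                counts = _nb_draws(rng_sc, mu, dispersion[:, None])
                blocks.append(sp.csc_matrix(counts.astype(np.int32)))
            mat = sp.hstack(blocks, format="csc") if blocks else sp.csc_matrix((G, 0))
            barcodes = [f"{lib_name}_cell{i:05d}" for i in range(n_cells)]
            libraries[lib_name] = CountMatrix(
                genes=gene_ids,
                columns=barcodes,
                counts=mat,
                column_groups=[t] * n_cells,
                column_library=[f"rep{r + 1}"] * n_cells,
            )

    # bulk replicates around the same perturbed proportions
    rng_bulk = np.random.default_rng(ss_bulk)
    bulk_cols, bulk_counts, bulk_groups, bulk_libs = [], [], [], []
    for t in ("typeA", "typeB"):
        for r in range(config.n_bulk_replicates):
            mu = props[(t, r)] * float(config.bulk_depth)
            bulk_counts.append(_nb_draws(rng_bulk, mu, config.bulk_dispersion))
            bulk_cols.append(f"{t}_bulk{r + 1}")
            bulk_groups.append(t)
            bulk_libs.append(f"rep{r + 1}")
    bulk = CountMatrix(
        genes=gene_ids,
        columns=bulk_cols,
        counts=np.column_stack(bulk_counts).astype(np.int64),
        column_groups=bulk_groups,
        column_library=bulk_libs,
    )

    return SimulatedExperiment(
        single_cell_libraries=libraries,
        bulk=bulk,
        truth=truth,
        gene_lengths=gene_lengths,
        config=config,
    )


def load_simulated_experiment(directory) -> SimulatedExperiment:
    """Load a bundle written by the ``simulate`` CLI command back into memory."""
    from pathlib import Path

    import yaml

    from .io import read_10x_mtx, read_counts_tsv, read_gene_lengths_tsv

    d = Path(directory)
    with open(d / "config.yaml") as fh:
        config = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in yaml.safe_load(fh).items()
        })
    libraries: dict[str, CountMatrix] = {}
    for lib_dir in sorted((d / "sc").iterdir()):
        cm = read_10x_mtx(
            lib_dir / "matrix.mtx", lib_dir / "features.tsv", lib_dir / "barcodes.tsv"
        )
        meta = pd.read_csv(lib_dir / "cells.tsv", sep="\t").set_index("barcode")
        meta = meta.reindex(list(cm.columns))
        libraries[lib_dir.name] = cm.with_labels(
            meta["group"].astype(str), meta["library"].astype(str)
        )
    bulk = read_counts_tsv(d / "bulk.tsv")
    samples = pd.read_csv(d / "bulk_samples.tsv", sep="\t").set_index("sample")
    samples = samples.reindex(list(bulk.columns))
    bulk = bulk.with_labels(samples["group"].astype(str), samples["library"].astype(str))
    truth = pd.read_csv(d / "truth.tsv", sep="\t")
    lengths = read_gene_lengths_tsv(d / "gene_lengths.tsv")
    return SimulatedExperiment(
        single_cell_libraries=libraries, bulk=bulk, truth=truth,
        gene_lengths=lengths, config=config,
    )


def _split_sizes(total: int, parts: int) -> list[int]:
    base = total // parts
    sizes = [base] * parts
    for i in range(total - base * parts):
        sizes[i] += 1
    return sizes


def truth_quartiles(truth: pd.DataFrame, bulk_de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Quartile labels (1-4) of the reference DEGs, three ways.

    Reference DEGs are the genes called at BH <= ``alpha`` in ``bulk_de``.
    Q1 holds the smallest unadjusted p-values, the largest |log2FC|, and the
    highest abundance (``mean_tpm``) respectively; ties break by ascending
    gene id.
    """
    missing = set(truth["gene_id"]) - set(bulk_de["gene_id"])
    if missing:
        raise SimulationError(f"bulk_de does not cover {len(missing)} truth genes")
    degs = call_degs(bulk_de, alpha=alpha, adjustment="bh")
    sub = bulk_de[bulk_de["gene_id"].isin(degs)].copy()
    if len(sub) < 4:
        raise SimulationError(f"only {len(sub)} reference DEGs; cannot form quartiles")
    return pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "q_p": assign_quartiles(sub["p_unadj"].to_numpy(), sub["gene_id"].to_numpy(), ascending=True),
            "q_abs_log2fc": assign_quartiles(
                np.abs(sub["log2fc"].to_numpy()), sub["gene_id"].to_numpy(), ascending=False
            ),
            "q_abundance": assign_quartiles(
                sub["mean_tpm"].to_numpy(), sub["gene_id"].to_numpy(), ascending=False
            ),
        }
    )
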