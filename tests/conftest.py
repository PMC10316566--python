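import numpy as np
import pytest

from degrecap.io import CountMatrix
from degrecap.simulate import SimulationConfig, simulate_paired_experiment


@pytest.fixture
def small_cm() -> CountMatrix:
    """3 genes x 4 cells, two groups, two libraries."""
    counts = np.array(
        [
            [1, 0, 3, 2],
            [0, 5, 0, 1],
            [2, 2, 4, 0],
        ]
    )
    return CountMatrix(
        genes=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "c4"],
        counts=counts,
        column_groups=["A", "A", "B", "B"],
        column_library=["L1", "L2", "L1", "L2"],
    )


@pytest.fixture(scope="session")
def tiny_experiment():
    """Small paired experiment reused by integration-style tests."""
    cfg = SimulationConfig(
        n_genes=800,
        n_cells_per_type=300,
        frac_de=0.25,
        bulk_depth=2_000_000,
        seed=42,
    )
    return simulate_paired_experiment(cfg)


def random_count_matrix(rng: np.random.Generator, n_genes: int, n_cols: int) -> CountMatrix:
    counts = rng.poisson(2.0, size=(n_genes, n_cols))
    return CountMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        columns=[f"c{j}" for j in range(n_cols)],
        counts=counts,
        column_groups=rng.choice(["A", "B"], size=n_cols),
        column_library=rng.choice(["L1", "L2"], size=n_cols),
    )
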