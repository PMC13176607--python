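import numpy as np
import pandas as pd
import pytest

from tapinto.dataset import ExpressionDataset
from tapinto.simulate import SimConfig, simulate


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes × (3 tumor + 1 normal) hand-written matrix."""
    values = pd.DataFrame(
        [[5.0, 9.0, 1.0, 2.0], [3.0, 3.0, 3.0, 3.0], [10.0, 9.0, 8.0, 4.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    roles = pd.Series(
        ["tumor", "tumor", "tumor", "normal"], index=["s1", "s2", "s3", "s4"]
    )
    return ExpressionDataset(values=values, roles=roles)


@pytest.fixture(scope="session")
def sim_pair():
    """A moderately sized simulated cohort with three planted genes."""
    cfg = SimConfig(
        n_tumor=100, n_normal=30, n_genes=30, planted_gene_fraction=0.1, seed=11
    )
    return simulate(cfg)


def random_dataset(rng: np.random.Generator, n_genes=8, n_tumor=6, n_normal=3):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_normal)]
    values = pd.DataFrame(
        rng.gamma(2.0, 10.0, size=(n_genes, n_tumor + n_normal)),
        index=genes,
        columns=samples,
    )
    roles = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    return ExpressionDataset(values=values, roles=roles)
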