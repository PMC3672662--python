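import numpy as np
import pandas as pd
import pytest

from parityomics.containers import ExpressionMatrix
from parityomics.datasets import load_transplant_tables
from parityomics.simulate import SimulationConfig, simulate_expression_dataset


@pytest.fixture(scope="session")
def transplant_tables():
    return load_transplant_tables()


@pytest.fixture(scope="session")
def small_expression():
    """2000-gene synthetic two-condition dataset with planted DE genes."""
    cfg = SimulationConfig(seed=11, n_genes=2000)
    return simulate_expression_dataset(cfg)


def make_expression(values: np.ndarray, n_virgin: int, n_parous: int) -> ExpressionMatrix:
    """Hand-rolled ExpressionMatrix from a genes x samples array."""
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"v{i}" for i in range(n_virgin)] + [f"p{i}" for i in range(n_parous)]
    cond = pd.Series(["virgin"] * n_virgin + ["parous"] * n_parous, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), cond)
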