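import numpy as np
import pandas as pd
import pytest

from coexnet.expression import ExpressionMatrix
from coexnet.synthetic_data import SimulationConfig, simulate_counts


@pytest.fixture
def make_matrix():
    """Factory for small in-memory expression matrices."""

    def _make(values, conditions, batches=None, scale="log_normalized"):
        values = np.asarray(values, float)
        genes = [f"g{i}" for i in range(values.shape[0])]
        samples = [f"s{j}" for j in range(values.shape[1])]
        if batches is None:
            batches = ["B1"] * len(samples)
        meta = pd.DataFrame({"condition": list(conditions), "batch": list(batches)},
                            index=pd.Index(samples, name="sample"))
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples), meta, scale)

    return _make


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_genes=400, n_tumor=10, n_normal=10, n_batches=2,
                            de_fraction=0.05, log2fc_effect=2.0,
                            core_module_size=10, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_counts(small_cfg)
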