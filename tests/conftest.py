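import numpy as np
import pandas as pd
import pytest

from cernapipe.models import DesignTable, ExpressionMatrix


@pytest.fixture
def design6():
    return DesignTable(
        {"H1": "HIGH", "H2": "HIGH", "H3": "HIGH", "L1": "LOW", "L2": "LOW", "L3": "LOW"}
    )


@pytest.fixture
def samples6():
    return ["H1", "H2", "H3", "L1", "L2", "L3"]


def make_matrix(values, layer="mRNA", unit="count", features=None, samples=None):
    values = np.asarray(values)
    features = features or [f"f{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), layer=layer, unit=unit
    )


@pytest.fixture
def small_sim():
    """One small planted simulation shared across tests (module-scoped cost)."""
    from cernapipe import SimConfig, simulate

    return simulate(SimConfig(seed=11, n_triplets=5, n_mrna=120, n_lncrna=80, n_mirna=40))
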