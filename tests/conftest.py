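import numpy as np
import pandas as pd
import pytest

from coexnet.data import AbundanceTable
from coexnet.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """300-protein synthetic study with one planted module, planted DE and
    subtype structure switched off so the module is the only co-expression
    signal."""
    cfg = SyntheticConfig(n_proteins=300, seed=11, subtype_effect=0.0, missing_fraction=0.0)
    table, network, truth, survival = generate_dataset(cfg)
    return cfg, table, network, truth, survival


@pytest.fixture(scope="session")
def subtype_dataset():
    """Dataset with the two-subtype axis active (markers shifted by 2)."""
    cfg = SyntheticConfig(n_proteins=400, seed=5, subtype_effect=2.0)
    table, network, truth, survival = generate_dataset(cfg)
    return cfg, table, network, truth, survival


def make_table(values: np.ndarray, n_case: int, n_ctrl: int, prefix: str = "g") -> AbundanceTable:
    """Wrap a raw matrix (proteins x samples) into an AbundanceTable with the
    first n_case columns labelled case."""
    p, n = values.shape
    assert n == n_case + n_ctrl
    samples = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(p)], columns=samples)
    design = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    return AbundanceTable(frame, design)
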