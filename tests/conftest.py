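import numpy as np
import pandas as pd
import pytest

from qsaropt.datagen import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with ground truth, shared across tests."""
    cfg = GeneratorConfig(
        n_samples=200, n_descriptors=60, sparse_fraction=0.25, n_informative=8, seed=42
    )
    table, gt = generate_dataset(cfg)
    return cfg, table, gt


@pytest.fixture()
def toy_table():
    """Hand-built descriptor table with known zero fractions and labels."""
    rng = np.random.default_rng(0)
    n = 20
    return pd.DataFrame(
        {
            "compound_id": [f"C{i}" for i in range(n)],
            "A": np.r_[np.zeros(n - 1), 1.0],            # zero fraction 0.95
            "B": rng.uniform(1, 5, n),                    # dense
            "C": np.r_[np.zeros(10), rng.uniform(size=10)],  # zero fraction 0.5
            "pIC50": rng.uniform(2, 9, n),
            "Caco2": rng.integers(0, 2, n),
            "CYP3A4": rng.integers(0, 2, n),
            "hERG": rng.integers(0, 2, n),
            "HOB": rng.integers(0, 2, n),
            "MN": rng.integers(0, 2, n),
        }
    )
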