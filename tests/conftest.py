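import numpy as np
import pytest

import uromarker as um


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic batch (20+20 samples, 200 features) with truth."""
    return um.generate_feature_table(um.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def clean_table(default_table):
    table, truth = default_table
    clean, report = um.preprocess_chain(table)
    return clean, truth, report


@pytest.fixture(scope="session")
def noise_free_table():
    """Degenerate settings: no QC noise, no drift, no class effect."""
    cfg = um.SimulationConfig(
        seed=7, effect_size=0.0, drift_fraction=0.0, qc_rsd=0.0
    )
    return um.generate_feature_table(cfg)


@pytest.fixture(scope="session")
def separable_xy():
    """Separable limit: every variable carries a 4 SD class effect on
    top of small noise, so any reasonable discriminant axis splits the
    classes with a huge margin."""
    rng = np.random.default_rng(3)
    n = 20
    y = np.array([1.0] * n + [-1.0] * n)
    X = 2.0 * y[:, None] * np.ones(10) + 0.3 * rng.normal(size=(2 * n, 10))
    X[:, 5:] *= -1.0  # half the variables point the other way
    return X, y


@pytest.fixture(scope="session")
def null_xy():
    """Pure-noise matrix with balanced labels (exchangeable)."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(40, 30))
    y = np.array([1.0] * 20 + [-1.0] * 20)
    return X, y
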