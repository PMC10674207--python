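import numpy as np
import pandas as pd
import pytest

from sludgesense.config import RunConfig, default_config


@pytest.fixture(scope="session")
def shipped_config() -> RunConfig:
    return default_config()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def state_frame() -> pd.DataFrame:
    """Deterministic synthetic state recordings for dataset-layer tests."""
    rng = np.random.default_rng(7)
    n = 200
    t = np.arange(n)
    return pd.DataFrame({
        "X1": 290 + 30 * np.sin(t / 9.0) + rng.normal(0, 2, n),
        "X2": 108 + 10 * np.cos(t / 13.0) + rng.normal(0, 1, n),
        "X3": 40 + 5 * np.sin(t / 7.0) + rng.normal(0, 0.5, n),
        "X4": 1.7 + 0.3 * np.cos(t / 11.0) + rng.normal(0, 0.05, n),
        "X5": 2.5 + 0.4 * np.sin(t / 5.0) + rng.normal(0, 0.05, n),
    })
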