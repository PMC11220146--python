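import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_classification_frame(n, n_informative, n_noise, effect, seed):
    """Gaussian feature matrix with a location shift on the informative
    columns for the positive class."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n // 2, replace=False)] = 1
    cols = {}
    for i in range(n_informative):
        cols[f"inf_{i:02d}"] = rng.normal(0, 1, n) + effect * y
    for i in range(n_noise):
        cols[f"noise_{i:02d}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), y


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered cohort shared by the image-level tests."""
    from pathoscore.synthetic import CohortConfig, generate_cohort

    config = CohortConfig(n_patients=6, seed=42)
    return generate_cohort(config)
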