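import numpy as np
import pandas as pd
import pytest

from vestlat import (
    DeficitConfig,
    MissingRates,
    SyntheticConfig,
    VhitBias,
    generate_cohort,
    generate_controls,
)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def clean_cfg() -> SyntheticConfig:
    """Default effects but no flips, no missingness, no outliers."""
    return SyntheticConfig(
        seed=7,
        p_flip=0.0,
        outlier_rate=0.0,
        missing_rates=MissingRates.null(),
    )


@pytest.fixture(scope="session")
def null_cfg() -> SyntheticConfig:
    """No deficit, no bias, no flips/outliers/missingness: fully symmetric."""
    return SyntheticConfig(
        seed=11,
        deficit=DeficitConfig.null(),
        vhit_bias=VhitBias.null(),
        missing_rates=MissingRates.null(),
        outlier_rate=0.0,
        p_flip=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_cfg):
    return generate_cohort(clean_cfg)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return generate_cohort(default_cfg), generate_controls(default_cfg)


def separable_features(n=24, gap=6.0, seed=0, n_noise=2) -> tuple[pd.DataFrame, np.ndarray]:
    """A tiny perfectly separated cohort: one informative column with a
    wide class gap plus pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = np.array([1, -1] * (n // 2))
    info = y * gap + rng.normal(0, 0.5, size=n)
    cols = {"info": info}
    for k in range(n_noise):
        cols[f"noise{k}"] = rng.normal(0, 1.0, size=n)
    return pd.DataFrame(cols), y
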