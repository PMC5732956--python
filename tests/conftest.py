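import numpy as np
import pandas as pd
import pytest

from mltobit import (
    CensoringSpec,
    DesignConfig,
    PopulationParams,
    TwoLevelDataset,
    apply_floor,
    generate_two_level,
)


@pytest.fixture(scope="session")
def canonical_params() -> PopulationParams:
    """The canonical generating parameters: gamma=(1, 0.75, 0.5), phi=0.5, sigma2=1."""
    return PopulationParams()


@pytest.fixture(scope="session")
def small_dataset() -> TwoLevelDataset:
    """3 clusters x 4 units, uncensored."""
    return generate_two_level(DesignConfig(n_clusters=3, cluster_size=4, seed=42))


@pytest.fixture(scope="session")
def floored_dataset() -> TwoLevelDataset:
    """10 clusters x 6 units, floored at -0.25 (roughly 20% censored)."""
    data = generate_two_level(DesignConfig(n_clusters=10, cluster_size=6, seed=7))
    return apply_floor(data, CensoringSpec(lower=-0.25))


@pytest.fixture(scope="session")
def medium_floored_dataset() -> TwoLevelDataset:
    """100 clusters x 10 at the heaviest standard floor (threshold 0.03)."""
    data = generate_two_level(DesignConfig(seed=2024))
    return apply_floor(data, CensoringSpec(lower=0.03))


def make_singleton_dataset(n: int = 60, seed: int = 5) -> TwoLevelDataset:
    """All clusters of size 1 (no between-variance identifiable)."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    y = 1.0 + 0.75 * x1 + 0.5 * x2 + rng.standard_normal(n) * 1.2
    frame = pd.DataFrame(
        {
            "cluster_id": np.arange(n),
            "y_obs": y,
            "censored_low": False,
            "censored_high": False,
            "x1": x1,
            "x2": x2,
        }
    )
    return TwoLevelDataset(frame=frame)
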