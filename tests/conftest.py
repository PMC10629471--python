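import numpy as np
import pytest

from tauspread import CohortConfig, generate_cohort


def small_config(seed: int = 7, **overrides) -> CohortConfig:
    """A reduced cohort: 4 networks, 40 parcels, 12 subjects per stratum."""
    base = dict(
        stratum_sizes=(12, 12, 12, 12),
        n_parcels=40,
        n_networks=4,
        n_true_epicentres=5,
        n_vulnerable_parcels=10,
        n_timepoints=120,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    tables, truth = generate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
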