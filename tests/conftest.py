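import numpy as np
import pytest

from srscluster import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-mouse chronic-phase cohort, fully deterministic."""
    cfg = SyntheticConfig(n_mice=30, seed=7)
    events, windows, gt = generate_cohort(cfg)
    return cfg, events, windows, gt


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without edge truncation: every cluster fully inside its window."""
    cfg = SyntheticConfig(n_mice=40, seed=11, allow_edge_truncation=False)
    events, windows, gt = generate_cohort(cfg)
    return cfg, events, windows, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
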