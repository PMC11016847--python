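import warnings

import numpy as np
import pandas as pd
import pytest

from buddormancy.simulate import default_config, simulate_experiment

warnings.filterwarnings("ignore", message=".*hourly readings.*")


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic experiment, shared across tests (seed 11)."""
    return simulate_experiment(default_config(seed=11))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default experiment with every noise term zeroed (exact-recovery oracle)."""
    cfg = default_config(seed=7)
    cfg.noise = cfg.noise.zeroed()
    return simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240301)


def isotopes_for_pipeline(bundle):
    """Rename generator isotope columns to the in-memory analysis names."""
    return bundle["isotopes"].rename(columns={"d2H_permil": "d2H", "d18O_permil": "d18O"})
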