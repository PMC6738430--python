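import numpy as np
import pandas as pd
import pytest

from telemeth import synthdata as sd


@pytest.fixture(scope="session")
def mini_dataset():
    """Small 16-stratum dataset with planted causal CpGs, shared across tests."""
    specs = sd.mini_specs(50)
    return sd.generate_cohorts(
        specs, n_probes=600, n_causal=10, seed=11, causal_effect_size=0.3
    )


@pytest.fixture(scope="session")
def mini_specs_list():
    return sd.mini_specs(50)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_stratum():
    """One 120-sample stratum with no families, for adjustment tests."""
    spec = sd.StratumSpec(
        "COH", "female", "European", "b1", 120, (30, 80), 7.0, 0.7, -0.3, 0.0
    )
    return sd.generate_cohorts([spec], n_probes=80, n_causal=0, seed=5)
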