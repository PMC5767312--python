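import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from droughtprime.pipeline import run_core
from droughtprime.simulate import SimulationConfig, noiseless, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated experiment (seed 1)."""
    config = SimulationConfig(seed=1)
    raw, samples, probe_map, truth = simulate_dataset(config)
    return config, raw, samples, probe_map, truth


@pytest.fixture(scope="session")
def default_bundle(default_dataset):
    """Full pipeline run on the default dataset."""
    _, raw, samples, probe_map, _ = default_dataset
    return run_core(raw, samples, probe_map)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noise-free experiment: observed values equal the planted cell means."""
    config = noiseless(SimulationConfig(n_genes=60, n_deg_per_class=1, n_primed_high=1,
                                        n_primed_low=1, n_init_only=2, seed=7))
    raw, samples, probe_map, truth = simulate_dataset(config)
    return config, raw, samples, probe_map, truth


def sheet_of(samples: pd.DataFrame) -> pd.DataFrame:
    return samples.set_index("sample_id")
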