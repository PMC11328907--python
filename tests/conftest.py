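import numpy as np
import pandas as pd
import pytest

from funcbiogeo import synthetic
from funcbiogeo.pipeline import PipelineConfig, run_synthetic_pipeline


@pytest.fixture(scope="session")
def env_specs():
    return synthetic.default_env_specs()


@pytest.fixture(scope="session")
def small_grid(env_specs):
    return synthetic.generate_env_grid(env_specs, grid_resolution=10.0, seed=7)


@pytest.fixture(scope="session")
def small_stations(small_grid):
    return synthetic.generate_stations(small_grid, n_stations=40, seed=7)


@pytest.fixture(scope="session")
def small_community(env_specs):
    genes, truth = synthetic.generate_community(
        n_mags=10, n_clusters=12, n_enzymes=3, seed=7, env_specs=env_specs
    )
    return genes, truth


@pytest.fixture(scope="session")
def small_counts(small_stations, small_community):
    _, truth = small_community
    return synthetic.simulate_reads(small_stations, truth, depth_per_station=20_000, seed=7)


@pytest.fixture(scope="session")
def recovery_pipeline():
    """Full synthetic study at the recovery-test conditions.

    130 stations, 4 climatology variables (8 model features), 40
    clusters with Gaussian niches, sequencing depth 1e5, low
    station-level noise, 20 bootstrap rounds. Shared across the tests
    that probe different facets of the same run.
    """
    return run_synthetic_pipeline(
        seed=4, config=PipelineConfig(n_boot=20, abundance_noise_sd=0.05)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_abundance():
    """5 stations x 4 clusters, rows summing to 1."""
    rng = np.random.default_rng(3)
    raw = rng.random((5, 4)) + 0.1
    rel = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, index=[f"S{i}" for i in range(1, 6)],
                        columns=[f"C{j}" for j in range(1, 5)])
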