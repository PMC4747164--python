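import numpy as np
import pytest

from foxochip.cli_pipeline import RunConfig, run_pipeline
from foxochip.synthetic_data import (
    SimulationConfig,
    simulate_chip,
    simulate_genome,
)


@pytest.fixture()
def small_config():
    """A genome small enough for fast unit tests (one chromosome, 20 genes)."""
    return SimulationConfig(
        seed=2, n_chroms=1, chrom_length=120_000, n_genes=20, reads_per_sample=20_000
    )


@pytest.fixture()
def small_sim(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def default_config():
    """The default study conditions of the generator."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def default_chip(default_config, default_sim):
    _, _, truth = default_sim
    return simulate_chip(default_config, truth)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run shared by the end-to-end tests."""
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(outdir=str(outdir), seed=1)
    summary = run_pipeline(config)
    return config, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
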