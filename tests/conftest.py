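import pytest

from sescape.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One full default-condition simulated dataset shared by the suite."""
    out = tmp_path_factory.mktemp("sim") / "seed11"
    return simulate(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A half-scale dataset for cheap end-to-end checks."""
    cfg = SimulationConfig(
        seed=5,
        n_genes=80,
        n_enhancer_sites=300,
        n_se_clusters=15,
    )
    out = tmp_path_factory.mktemp("sim_small") / "seed5"
    return simulate(cfg, out)
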