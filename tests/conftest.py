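import pytest

from homeocomp.synthetic import SimulationConfig, simulate_experiment, write_fixtures


@pytest.fixture(scope="session")
def small_experiment():
    """A small hexaploid experiment with both mutation classes."""
    config = SimulationConfig(
        n_groups=40,
        ptc_fraction=0.5,
        syn_fraction=0.25,
        nmd_fold=0.1,
        compensation_rate=0.5,
        compensation_fold=2.0,
        nb_dispersion=0.05,
        seed=42,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def fixture_dir(small_experiment, tmp_path_factory):
    directory = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(small_experiment, directory)
    return directory, paths
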