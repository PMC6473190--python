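import numpy as np
import pytest

from capture_atlas.io import read_fasta, write_fasta
from capture_atlas.simulate import (
    SimulationConfig,
    simulate_genome_and_annotation,
    simulate_long_reads,
    simulate_short_read_junctions,
)


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment shared across the suite."""
    return simulate_genome_and_annotation(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_reads(default_experiment):
    return simulate_long_reads(default_experiment)


@pytest.fixture(scope="session")
def default_junctions(default_experiment):
    return simulate_short_read_junctions(default_experiment)


@pytest.fixture(scope="session")
def default_genome(default_experiment, tmp_path_factory):
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    write_fasta(default_experiment.sequences, str(path))
    return read_fasta(str(path))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
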