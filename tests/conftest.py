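import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from delscan.formats_io import Phylogeny
from delscan.lrt import CodonModelParams
from delscan.simulate import random_tree, simulate_toy_genome, uniform_pi

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_tree() -> Phylogeny:
    """Five-taxon tree with moderate branch lengths."""
    return Phylogeny.from_newick(
        "((sp1:0.3,sp2:0.2):0.15,(sp3:0.25,sp4:0.35):0.1,sp5:0.4);"
    )


@pytest.fixture(scope="session")
def uniform_params() -> CodonModelParams:
    return CodonModelParams(2.0, 1.0, 1.0, uniform_pi())


@pytest.fixture(scope="session")
def big_tree() -> Phylogeny:
    """Twenty taxa, total branch length 2: the calibration frame."""
    return random_tree(20, 2.0, seed=11)


@pytest.fixture(scope="session")
def toy_genome():
    return simulate_toy_genome(n_samples=4, seed=0)


@pytest.fixture()
def toy_genome_paths(toy_genome, tmp_path):
    return toy_genome.write(str(tmp_path))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
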