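import numpy as np
import pytest

from icmsim.lattice import build_lattice
from icmsim.params import ParameterSet


@pytest.fixture(scope="session")
def map_params() -> ParameterSet:
    """The frozen wild-type MAP parameter set."""
    return ParameterSet()


@pytest.fixture(scope="session")
def lattice_5x5():
    return build_lattice(5, 5)


@pytest.fixture(scope="session")
def lattice_2x2():
    return build_lattice(2, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def erk_only_params() -> ParameterSet:
    """Parameters that isolate the ERK synthesis/degradation birth-death
    module: with no basal transcription and an empty initial state, no gene
    can ever activate, so inactive ERK is the only evolving species."""
    return ParameterSet(c_basal=0.0, c_find=1.0, mean_init_mrna=0.0,
                        mean_init_protein=0.0)
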