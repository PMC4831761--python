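import numpy as np
import pandas as pd
import pytest

from pbme.dynamics import TimeSeriesDataset
from pbme.knowledge_library import parse_library
from pbme.model_space import enumerate_structures, parse_incomplete_model
from pbme.synthetic_data import packaged_text


@pytest.fixture(scope="session")
def pp_library():
    """The packaged Predator-Prey domain-knowledge library."""
    return parse_library(packaged_text("predator_prey.pbl"))


@pytest.fixture(scope="session")
def pp_incomplete():
    """The packaged incomplete model: growth and interaction left open."""
    return parse_incomplete_model(packaged_text("predator_prey.pbm"))


@pytest.fixture(scope="session")
def pp_structures(pp_library, pp_incomplete):
    return enumerate_structures(pp_library, pp_incomplete)


@pytest.fixture(scope="session")
def decay_incomplete():
    return parse_incomplete_model(
        "incomplete model DecayOnly { entity x : Population; process decay : Decay(pop = x); }"
    )


@pytest.fixture(scope="session")
def decay_structure(pp_library, decay_incomplete):
    (structure,) = enumerate_structures(pp_library, decay_incomplete)
    return structure


def make_decay_dataset(rate: float = 0.5, x0: float = 100.0, t_stop: float = 10.0, step: float = 1.0):
    t = np.arange(0.0, t_stop + step / 2, step)
    return TimeSeriesDataset(
        pd.DataFrame({"t": t, "x.d": x0 * np.exp(-rate * t)}), endogenous=("x.d",)
    )


@pytest.fixture()
def decay_dataset():
    return make_decay_dataset()
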