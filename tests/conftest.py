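import pytest

from irfgrn.engine import Marking, SimulationConfig
from irfgrn.model import PetriNetModel, Place, Transition, build_default_irf_grn


@pytest.fixture(scope="session")
def default_model() -> PetriNetModel:
    return build_default_irf_grn()


@pytest.fixture(scope="session")
def chain_model() -> PetriNetModel:
    """Minimal source -> transition -> sink net with a known flow mean."""
    return PetriNetModel(
        [
            Place("S", klass="transcription_factor", is_entry=True),
            Place("K", klass="output_gene", is_output=True),
        ],
        [Transition("t", ("S",), (), ("K",))],
        {"name": "chain"},
    )


@pytest.fixture
def chain_marking() -> Marking:
    return Marking({"S": 100})


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Small but adequate settings for qualitative (positivity) checks."""
    return SimulationConfig(n_blocks=30, n_runs=10, summary_window=10, seed=5)
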