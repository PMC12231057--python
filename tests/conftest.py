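import numpy as np
import pytest

from relfusion.models import build_ce_model, build_rc_model
from relfusion.puzzles import make_puzzle_set
from relfusion.synth import GeneratorConfig, simulate_behaviour


@pytest.fixture(scope="session")
def cfg():
    """Default study configuration with a fixed seed."""
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def puzzles(cfg):
    return cfg.puzzle_set("fmri")


@pytest.fixture(scope="session")
def behaviour(puzzles, cfg):
    return simulate_behaviour(puzzles, cfg, arm="fmri")


@pytest.fixture(scope="session")
def rc_model(puzzles):
    return build_rc_model(puzzles)


@pytest.fixture(scope="session")
def ce_model(behaviour):
    return build_ce_model(behaviour)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
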