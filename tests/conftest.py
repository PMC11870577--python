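import numpy as np
import pytest

from aspdyn.model import simulate


@pytest.fixture(scope="session")
def trajectories():
    """Default-parameter simulations of every treatment arm (72 h, 0.5 h grid).

    Session-scoped: the model is deterministic, so one integration per arm
    serves every test.
    """
    presets = (
        "vehicle",
        "aa5",
        "aa5_uridine",
        "aa5_rotenone",
        "aa5_rot_succinate",
        "aa5_rot_succ_uridine",
        "aa5_aspartate",
    )
    return {name: simulate(scenario=name) for name in presets}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
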