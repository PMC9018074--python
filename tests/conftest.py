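import pytest

from ctboolsim import SimulationConfig
from ctboolsim.synthetic import make_toy_model


@pytest.fixture(scope="session")
def telegraph():
    return make_toy_model("telegraph", u=2.0, d=1.0)


@pytest.fixture(scope="session")
def cascade():
    return make_toy_model("cascade", length=3)


@pytest.fixture(scope="session")
def mini_tumour():
    return make_toy_model("mini_tumour")


@pytest.fixture()
def growth_config():
    """Growth-factor ON, death signal OFF; fast-converging toy horizon."""
    return SimulationConfig(
        n_trajectories=2000,
        max_time=8.0,
        time_tick=1.0,
        seed=42,
        initial={"GrowthFactor": 1.0, "DeathSignal": 0.0},
    )
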