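import pytest

from mlpgg.game import (
    Action,
    ActionProfile,
    BALANCED,
    GLOBAL_BOOST,
    GLOBAL_ONLY,
)
from mlpgg.simulate import SimConfig, generate_dataset

G = Action.INVEST_GLOBAL
L = Action.INVEST_OWN_LOCAL
O = Action.INVEST_OTHER_LOCAL
K = Action.KEEP


def profile(*actions):
    return ActionProfile(tuple(actions))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic experiment shared by analysis tests: 12 groups per
    condition, default behavioural parameters."""
    return generate_dataset(SimConfig(n_groups_per_condition=12, seed=20260919))


@pytest.fixture(scope="session")
def conditions():
    return {"global_only": GLOBAL_ONLY, "balanced": BALANCED, "global_boost": GLOBAL_BOOST}
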