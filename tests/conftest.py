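import numpy as np
import pandas as pd
import pytest

from metaconf import SimConfig, TrialTable, generate_cohort


def make_table(rows, chance_map=None):
    df = pd.DataFrame(
        rows,
        columns=["agent_id", "agent_group", "condition", "item_id", "correct", "confidence"],
    )
    return TrialTable(df, chance_map) if chance_map else TrialTable(df)


@pytest.fixture
def tiny_table():
    """One agent, four trials: correct {1,1,0,1}, confidence {80,90,40,70}."""
    return make_table(
        [
            ("a1", "human", "2C", "q1", 1, 80),
            ("a1", "human", "2C", "q2", 1, 90),
            ("a1", "human", "2C", "q3", 0, 40),
            ("a1", "human", "2C", "q4", 1, 70),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group cohort (87 agents x 60 items), seed 1."""
    return generate_cohort(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for pipeline tests: 12 agents/group, 6 items/condition."""
    return generate_cohort(SimConfig(n_agents_per_group=12, n_items_per_condition=6), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
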