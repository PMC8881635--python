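import numpy as np
import pandas as pd
import pytest

import moralsv as m
from moralsv.data import FINANCIAL, MORAL


@pytest.fixture(scope="session")
def financial_design():
    return m.build_design(FINANCIAL)


@pytest.fixture(scope="session")
def moral_design():
    return m.build_design(MORAL)


@pytest.fixture(scope="session")
def agent():
    return m.sample_agent(m.PopulationConfig(), seed=7, subject_id="sub-01")


@pytest.fixture(scope="session")
def financial_dataset(agent, financial_design):
    return m.simulate_choices(agent, financial_design, seed=11)


@pytest.fixture(scope="session")
def moral_dataset(agent, moral_design):
    return m.simulate_choices(agent, moral_design, seed=13)


def make_dataset(task, magnitudes, perceived, chose, rt=None, sv=None, levels=None):
    """Hand-build a ChoiceDataset from parallel sequences."""
    n = len(magnitudes)
    trials = pd.DataFrame(
        {
            "magnitude": np.asarray(magnitudes, float),
            "level": levels if levels is not None else np.arange(1, n + 1),
            "perceived": np.asarray(perceived, float),
            "sv_target": sv if sv is not None else np.asarray(magnitudes, float),
            "chose_target": np.asarray(chose, bool),
            "rt_ms": rt if rt is not None else np.full(n, 1000.0),
        }
    )
    return m.ChoiceDataset(subject_id="hand", task=task, trials=trials)
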