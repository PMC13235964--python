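import numpy as np
import pandas as pd
import pytest

from coxmgm.datamodel import MixedDataset, VariableSpec, validate_dataset
from coxmgm.simulate import SimulationConfig, generate_dag, simulate_mixed_data


def make_mixed(n=200, seed=0, r=1):
    """Small hand-built dataset: 2 continuous, 1 three-level discrete,
    r censored variables, all mutually independent."""
    rng = np.random.default_rng(seed)
    cont = rng.normal(size=(n, 2))
    disc = rng.integers(0, 3, size=(n, 1))
    times = rng.exponential(1.0, size=(n, r))
    cens = rng.exponential(2.0, size=(n, r))
    events = (times <= cens).astype(np.int64)
    obs = np.minimum(times, cens)
    return MixedDataset(
        sample_ids=[str(i) for i in range(n)],
        continuous=cont,
        discrete=disc,
        times=obs,
        events=events,
        continuous_names=["U", "V"],
        discrete_names=["G"],
        censored_names=[f"T{m}" for m in range(r)],
        levels=[("a", "b", "c")],
    )


@pytest.fixture
def small_mixed():
    return make_mixed()


@pytest.fixture(scope="session")
def sim_11():
    """11-node benchmark draw: 5 continuous, 5 discrete, 1 censored."""
    model = generate_dag(SimulationConfig(n_nodes=11, avg_degree=2,
                                          n_samples=1000, censoring="light", seed=3))
    data, _ = simulate_mixed_data(model)
    return data, model


@pytest.fixture
def raw_table():
    return pd.DataFrame({
        "x": [0.1, 0.5, -1.0, 2.0, 0.3],
        "g": ["A", "B", "A", "B", "A"],
        "t": [1.0, 2.0, 0.5, 3.0, 1.5],
        "d": [1, 0, 1, 1, 0],
    })


@pytest.fixture
def raw_specs():
    return [
        VariableSpec("x", "continuous"),
        VariableSpec("g", "discrete", levels=("A", "B")),
        VariableSpec("surv", "censored", time_col="t", event_col="d"),
    ]
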