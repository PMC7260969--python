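import numpy as np
import pandas as pd
import pytest

from acttime.task import TaskSpec, generate_design
from acttime.synth import BehaviorGroundTruth, simulate_behavior


@pytest.fixture(scope="session")
def spec():
    return TaskSpec()


@pytest.fixture(scope="session")
def truth():
    return BehaviorGroundTruth()


@pytest.fixture(scope="session")
def large_session(spec, truth):
    """2,000 simulated trials for parameter-recovery checks."""
    design = generate_design(spec, 2000, 0.1, seed=11)
    return simulate_behavior(design, truth, spec, seed=12)


@pytest.fixture(scope="session")
def small_session(spec, truth):
    """A study-sized session (150 trials)."""
    design = generate_design(spec, 150, 0.1, seed=21)
    return simulate_behavior(design, truth, spec, seed=22)


def make_chain_data(weights, n, sd, seed, labels=None):
    """Data from a linear chain/graph x_child = sum w * x_parent + noise."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = sorted({a for a, _ in weights} | {b for _, b in weights})
    data = {}
    order = []
    pending = list(labels)
    while pending:
        for node in list(pending):
            parents = [a for (a, b) in weights if b == node]
            if all(p in data for p in parents):
                x = rng.normal(0.0, sd, n)
                for (a, b), w in weights.items():
                    if b == node:
                        x = x + w * data[a]
                data[node] = x
                order.append(node)
                pending.remove(node)
    return pd.DataFrame(data)[list(labels)]
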