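import numpy as np
import pandas as pd
import pytest

from nresponse import TrialTable, generate_experiment

RATES = np.array([0.0, 67.0, 134.0, 201.0, 268.0])


def make_table(rows):
    return TrialTable(pd.DataFrame(rows, columns=["year", "rotation", "crop", "n_rate", "rep", "yield"]))


@pytest.fixture
def balanced_group():
    """One clean (year, rotation) corn group: 5 rates x 4 reps, mild noise."""
    rng = np.random.default_rng(11)
    rows = []
    for rate in RATES:
        mu = 4000 + 50 * rate - 0.09 * rate**2
        for rep in range(1, 5):
            rows.append([2001, "CC", "corn", rate, rep, mu * (1 + rng.normal(0, 0.03))])
    return make_table(rows)


@pytest.fixture(scope="session")
def experiment16():
    """A default 16-year synthetic experiment, shared across tests."""
    return generate_experiment(16, seed=123)
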