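import numpy as np
import pytest

from gepqsar.dataset import load_table1_fixture, load_table1_printed
from gepqsar.mlr import LinearModel, SelectionTrace


@pytest.fixture(scope="session")
def records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def printed():
    return load_table1_printed()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240311)


def make_trace(r2_values, n=30):
    """A synthetic selection trace with the given R² sequence."""
    models = [
        LinearModel(
            descriptors=[f"d{j+1}" for j in range(k + 1)],
            coefficients=np.zeros(k + 1),
            intercept=0.0,
            r2=r2,
            s2=0.0,
            n=n,
        )
        for k, r2 in enumerate(r2_values)
    ]
    return SelectionTrace(models=models)
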