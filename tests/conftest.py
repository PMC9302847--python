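import numpy as np
import pytest

from ddrkit import ConditionPair, ResponseSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def pair():
    return ConditionPair("a", "b")


def make_response_set(a_trials, b_trials, neuron_ids=None):
    """Build a two-condition ResponseSet from raw trial matrices."""
    a = np.atleast_2d(np.asarray(a_trials, dtype=float))
    b = np.atleast_2d(np.asarray(b_trials, dtype=float))
    ids = neuron_ids or tuple(f"n{i + 1}" for i in range(a.shape[1]))
    return ResponseSet(
        counts=np.vstack([a, b]),
        condition_labels=("a",) * a.shape[0] + ("b",) * b.shape[0],
        neuron_ids=ids,
    )


@pytest.fixture
def small_rs():
    """4 trials, 2 neurons, labels a,a,b,b."""
    return make_response_set([[0.0, 0.0], [2.0, 2.0]], [[1.0, 0.0], [1.0, 2.0]])
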