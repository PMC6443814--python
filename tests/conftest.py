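import numpy as np
import pytest

from dynforage.schedule import SessionData


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_session(choices, rewards, block_id=None, free=None, meta=None):
    """Build a SessionData from plain sequences (all trials free by default)."""
    choices = np.asarray(choices, dtype=np.int8)
    n = len(choices)
    rewards = np.asarray(rewards, dtype=np.int8)
    if block_id is None:
        block_id = np.zeros(n, dtype=np.int64)
    if free is None:
        free = np.ones(n, dtype=bool)
    return SessionData(
        choice=choices,
        reward=rewards,
        free_choice=np.asarray(free, dtype=bool),
        block_id=np.asarray(block_id, dtype=np.int64),
        meta=dict(meta or {}),
    )


@pytest.fixture
def toy_session():
    """Two-block session with hand-countable fractions."""
    # block 0: 8 G choices (6 rewarded), 2 R choices (1 rewarded)
    # block 1: 5 G, 5 R, one reward each side
    choices = [1] * 8 + [0] * 2 + [1] * 5 + [0] * 5
    rewards = [1] * 6 + [0] * 2 + [1, 0] + [1, 0, 0, 0, 0] + [1, 0, 0, 0, 0]
    block = [0] * 10 + [1] * 10
    return make_session(choices, rewards, block)
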