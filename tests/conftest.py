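import numpy as np
import pytest

from synstrain.popsim import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_seq(rng):
    """Factory for random ACGT sequences of a given length."""

    def make(length: int) -> str:
        return random_sequence(length, rng)

    return make


def substitute(seq: str, pos: int) -> str:
    """Replace the base at pos with a different one (deterministic)."""
    order = "ACGT"
    new = order[(order.index(seq[pos]) + 1) % 4]
    return seq[:pos] + new + seq[pos + 1 :]
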