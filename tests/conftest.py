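import numpy as np
import pytest

from mibni import BooleanFunction, BooleanNetwork, Gate, Trajectory


@pytest.fixture
def toggle_net():
    """Two mutually negating nodes: a' = NOT b, b' = NOT a."""
    return BooleanNetwork(
        [
            BooleanFunction((1,), (-1,), Gate.OR),
            BooleanFunction((0,), (-1,), Gate.OR),
        ]
    )


@pytest.fixture
def random_trajectory():
    def make(n_genes: int, T: int, seed: int) -> Trajectory:
        rng = np.random.default_rng(seed)
        return Trajectory(rng.integers(0, 2, size=(T, n_genes)))

    return make
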