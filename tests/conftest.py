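import numpy as np
import pytest

from apca import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples, two controls and two cases."""
    values = np.array([
        [1.0, 2.0, 5.0, 6.0],
        [2.0, 1.0, 6.0, 5.0],
        [3.0, 3.0, 3.0, 3.5],
    ])
    return ExpressionMatrix(values, ["p1", "p2", "p3"],
                            ["s1", "s2", "s3", "s4"],
                            ["control", "control", "case", "case"])


@pytest.fixture
def random_labelled(rng=None):
    """Factory for random labelled matrices of modest size."""
    def make(m=50, n=6, d=4, seed=0):
        r = np.random.default_rng(seed)
        values = r.normal(10.0, 2.0, size=(m, n + d))
        return ExpressionMatrix(
            values,
            [f"p{i}" for i in range(m)],
            [f"s{j}" for j in range(n + d)],
            ["control"] * n + ["case"] * d,
        )
    return make
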