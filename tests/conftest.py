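import numpy as np
import pytest

from crossbic import CountMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    values = rng.poisson(2.0, size=(8, 6)).astype(float)
    values[0, 0] = 5.0  # guarantee no all-zero cell
    return CountMatrix(
        values,
        [f"g{i}" for i in range(8)],
        [f"c{j}" for j in range(6)],
    )
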