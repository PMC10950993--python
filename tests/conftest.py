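import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_valid_states(rng, n, N_range=(2, 500)):
    """Random three-type states and positive fitness/mutation parameters."""
    out = []
    for _ in range(n):
        N = int(rng.integers(*N_range))
        cuts = np.sort(rng.integers(0, N + 1, size=2))
        counts = (int(cuts[0]), int(cuts[1] - cuts[0]), int(N - cuts[1]))
        fit = tuple(float(f) for f in rng.uniform(0.05, 5.0, size=3))
        r_m = float(rng.uniform(0.0, 1.0))
        out.append((counts, fit, r_m))
    return out
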