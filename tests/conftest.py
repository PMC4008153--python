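import numpy as np
import pytest

from peakshape.simulate import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-peak simulated experiment with planted changes (shared, read-only)."""
    cfg = SimConfig(n_peaks=300, n_affinity_changes=15, n_profile_changes=15)
    return simulate_experiment(cfg, repetition_seed=7)


def naive_mmd(a, b, sigma):
    """Triple-nested-loop biased MMD oracle (independent of the library path)."""
    import math

    def ksum(x, y):
        tot = 0.0
        for xi in x:
            for yj in y:
                tot += math.exp(-((xi - yj) ** 2) / (2.0 * sigma**2))
        return tot

    m, n = len(a), len(b)
    mmd2 = ksum(a, a) / m**2 - 2.0 * ksum(a, b) / (m * n) + ksum(b, b) / n**2
    return math.sqrt(max(mmd2, 0.0))
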