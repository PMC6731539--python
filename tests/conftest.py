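import numpy as np
import pytest

from eaload.bursts import Burst


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_burst(start: float, n_spikes: int, isi: float, jitter: float = 0.0,
               rng: np.random.Generator | None = None) -> Burst:
    """Construct a burst with roughly regular spacing (optionally jittered)."""
    times = start + np.arange(n_spikes) * isi
    if jitter > 0 and rng is not None:
        times = times + rng.uniform(0, jitter, size=n_spikes)
        times.sort()
    return Burst(tuple(times.tolist()))


@pytest.fixture
def planted_burst_populations(rng):
    """Three planted burst populations spanning distinct spike-load regimes.

    short/sparse (low load), intermediate, and long/dense (high load);
    returns (bursts, labels).
    """
    bursts, labels = [], []
    t = 0.0
    for _ in range(60):
        n = int(rng.integers(5, 8))
        bursts.append(make_burst(t, n, isi=2.0, jitter=0.3, rng=rng))
        labels.append(0)
        t += 60.0
    for _ in range(60):
        n = int(rng.integers(10, 16))
        bursts.append(make_burst(t, n, isi=0.9, jitter=0.25, rng=rng))
        labels.append(1)
        t += 60.0
    for _ in range(60):
        n = int(rng.integers(30, 60))
        bursts.append(make_burst(t, n, isi=0.25, jitter=0.1, rng=rng))
        labels.append(2)
        t += 120.0
    return bursts, np.array(labels)
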