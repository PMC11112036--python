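import numpy as np
import pytest

from stripmea.bursts import Burst, BurstParams


def brute_force_bursts(times, params: BurstParams | None = None):
    """Independent burst enumerator: check every contiguous run directly.

    O(n^2) scan over all candidate windows; keeps a run only when every
    internal ISI satisfies the criterion, the run is at least min_spikes
    long, and it cannot be extended on either side (maximality).
    """
    params = params or BurstParams()
    t = list(times)
    max_isi = params.max_isi_ms / 1000.0
    n = len(t)
    out = []
    for i in range(n):
        for j in range(i + params.min_spikes - 1, n):
            if all(t[k + 1] - t[k] <= max_isi for k in range(i, j)):
                left_ext = i > 0 and t[i] - t[i - 1] <= max_isi
                right_ext = j < n - 1 and t[j + 1] - t[j] <= max_isi
                if not left_ext and not right_ext:
                    out.append(
                        Burst(start=t[i], end=t[j], n_spikes=j - i + 1, first_index=i)
                    )
    return out


@pytest.fixture
def burst_oracle():
    return brute_force_bursts


@pytest.fixture
def rng():
    return np.random.default_rng(20240509)


def random_train(rng, max_spikes=30, span=2.0):
    """Random sorted spike train with ISIs straddling the 50 ms criterion."""
    n = int(rng.integers(0, max_spikes))
    t = np.sort(rng.uniform(0, span, n))
    # de-duplicate to strict increase
    return np.unique(t)
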