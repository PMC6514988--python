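import numpy as np
import pytest

import insolegait as ig


@pytest.fixture(scope="session")
def sim_config():
    return ig.SimulatorConfig()


@pytest.fixture(scope="session")
def walking_recording(sim_config):
    """One clean 10-step walking recording with ground truth (no artifacts)."""
    from dataclasses import replace

    cfg = replace(sim_config, artifact_prob=0.0)
    return ig.simulate_recording(cfg, ig.GaitType.WALKING, 10, seed=3)


@pytest.fixture(scope="session")
def small_samples(sim_config):
    """420 one-step samples (60 per class) from the default simulator."""
    return ig.simulate_samples(sim_config, n_per_class=4, steps_per_recording=15, k=1, seed=11)


def left_pressure_from_sums(sums, n_active=None):
    """Build a (frames, 16) pressure array realizing given left-foot sums.

    Each sum s is spread over min(s, 2) channels when n_active is None, or
    exactly n_active[i] channels (each >= 1, total == s) when given.
    """
    sums = list(sums)
    out = np.zeros((len(sums), 16), dtype=np.int64)
    for i, s in enumerate(sums):
        k = n_active[i] if n_active is not None else min(int(s), 2)
        if s == 0:
            continue
        base, extra = divmod(int(s), k)
        for c in range(k):
            out[i, c] = base + (1 if c < extra else 0)
    return out
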