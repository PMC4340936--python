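import numpy as np
import pytest

from fnoverlap import preprocess, synthio
from fnoverlap.formats import BrainMask


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 4-network cohort used by several module tests (built once)."""
    truth = synthio.demo_truth(
        n_networks=4, overlap_spec=((0, 1),), conditions=("taskA", "taskB"),
        seed=7, snr=1.0,
    )
    design = synthio.make_design(
        "block", n_events=8, seed=7, conditions=truth.conditions
    )
    volumes = synthio.simulate_cohort(truth, design, 4, seed=7)
    mask = preprocess.compute_mask(volumes)
    return truth, design, volumes, mask


@pytest.fixture()
def full_mask():
    return BrainMask(np.ones((6, 5, 4), dtype=np.uint8))


def planted_in_mask(truth, mask):
    """Planted maps as in-mask vectors (mask scan order)."""
    return np.stack([
        preprocess.to_matrix(m.values[..., None], mask)[0]
        for m in truth.networks
    ])


def bh_oracle(pvals, level):
    """Brute-force Benjamini-Hochberg: reject p <= p_(k) for the largest k
    with p_(k) <= level * k / m, checking every threshold explicitly."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.sort(p)
    k_best = 0
    for i in range(m):
        if order[i] <= level * (i + 1) / m:
            k_best = i + 1
    if k_best == 0:
        return np.zeros(m, dtype=bool)
    return p <= order[k_best - 1]
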