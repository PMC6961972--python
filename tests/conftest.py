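import numpy as np
import pandas as pd
import pytest

from neuroasym import PairedTable, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by read-only tests."""
    return generate_cohort(default_config(n_participants=200, seed=42))


@pytest.fixture()
def tiny_paired():
    """Two participants, one region: the hand-computable worked example."""
    data = pd.DataFrame({
        "participant_id": ["a", "b"],
        "region": ["bankssts", "bankssts"],
        "L": [2.0, 1.0],
        "R": [1.0, 2.0],
    })
    return PairedTable(metric="thickness", data=data)


def random_paired(seed, n_participants=10, n_regions=5, metric="thickness"):
    """Random positive paired table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    regions = [f"r{i}" for i in range(n_regions)]
    rows = []
    for i in range(n_participants):
        for r in regions:
            base = rng.uniform(1.0, 5.0)
            da = rng.normal(scale=0.3)
            rows.append({"participant_id": f"p{i}", "region": r,
                         "L": base + da / 2, "R": base - da / 2})
    return PairedTable(metric=metric, data=pd.DataFrame(rows))
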