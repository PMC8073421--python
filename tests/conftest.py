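import numpy as np
import pandas as pd
import pytest

from grtime.io_formats import CountsTable
from grtime.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7, n_up=30, n_down=30, n_null=240)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One small synthetic dataset shared across tests (read-only)."""
    ann, counts, expr_truth, peaksets, tracks, chip_truth = simulate_dataset(small_cfg)
    return {
        "cfg": small_cfg,
        "ann": ann,
        "counts": counts,
        "expr_truth": expr_truth,
        "peaksets": peaksets,
        "tracks": tracks,
        "chip_truth": chip_truth,
    }


@pytest.fixture()
def tiny_counts() -> CountsTable:
    counts = pd.DataFrame(
        {
            "t0_r1": [10.0, 5.0, 1.0],
            "t0_r2": [12.0, 4.0, 2.0],
            "t1_r1": [30.0, 5.0, 1.0],
            "t1_r2": [28.0, 6.0, 2.0],
        },
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {"time_hours": [0.0, 0.0, 1.0, 1.0], "replicate": [1, 2, 1, 2]},
        index=counts.columns,
    )
    return CountsTable(counts, meta)
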