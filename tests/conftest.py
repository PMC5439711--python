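import dataclasses

import numpy as np
import pandas as pd
import pytest

from epiclone import io_core
from epiclone.io_core import BandMatrix, SampleFrame, SsrTable
from epiclone.simulate import SimulationConfig


@pytest.fixture
def small_samples() -> SampleFrame:
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "x": [0, 0, 1, 5],
            "y": [0, 1, 0, 5],
            "stage": ["flowering", "vegetative", "flowering", "vegetative"],
            "genet_id": pd.array([1, 1, 2, 3], dtype="Int64"),
            "cover_x": [np.nan] * 4,
        }
    )
    return SampleFrame(df)


@pytest.fixture
def full_cover():
    """Uniform category-2 cover over a 20 m plot plus ring."""
    rows = [
        {"qx": qx, "qy": qy, "category": 2}
        for qx in range(-1, 21)
        for qy in range(-1, 21)
    ]
    return io_core.CoverGrid(pd.DataFrame(rows))


@pytest.fixture
def band_pair():
    """Paired HpaII / MspI matrices covering all four conditions plus missing."""
    samples = ["s1", "s2", "s3", "s4", "s5"]
    frags = ["f1", "f2"]
    hpa = pd.DataFrame(
        [[1, 0], [0, 1], [1, 1], [0, 0], [np.nan, 1]],
        index=pd.Index(samples, name="sample_id"), columns=frags, dtype=float,
    )
    msp = pd.DataFrame(
        [[1, 0], [1, 0], [0, 1], [0, 1], [1, 0]],
        index=pd.Index(samples, name="sample_id"), columns=frags, dtype=float,
    )
    return (
        BandMatrix("HpaII", "P1", hpa),
        BandMatrix("MspI", "P1", msp),
    )


@pytest.fixture
def small_ssr() -> SsrTable:
    df = pd.DataFrame(
        {
            "LocA.1": [100.0, 100.0, 102.0, 104.0],
            "LocA.2": [102.0, 102.0, 102.0, 106.0],
            "LocB.1": [200.0, 200.0, 204.0, 200.0],
            "LocB.2": [204.0, 204.0, 204.0, 202.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SsrTable(df)


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(), n_msap_loci=8, seed=3)
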