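import numpy as np
import pandas as pd
import pytest

from lcsm.data_io import LongitudinalDataset
from lcsm.model_zoo import StudyDesign, design_from_data
from lcsm.synthetic_data import (
    gfactor_generating_preset,
    mutualism_generating_preset,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    """Unit-scale three-wave design with no reliability adjustment."""
    return StudyDesign()


@pytest.fixture(scope="session")
def mutualism_cfg():
    """Mutualism generating conditions at a clearly detectable coupling."""
    return mutualism_generating_preset(0.3, 227, seed=11)


@pytest.fixture(scope="session")
def mutualism_data(mutualism_cfg):
    return simulate_dataset(mutualism_cfg)


@pytest.fixture(scope="session")
def mutualism_design(mutualism_cfg, mutualism_data):
    return design_from_data(
        mutualism_data, reliabilities=mutualism_cfg.design.reliabilities
    )


@pytest.fixture(scope="session")
def gfactor_cfg():
    return gfactor_generating_preset(0.1, 227, seed=13)


@pytest.fixture(scope="session")
def gfactor_data(gfactor_cfg):
    return simulate_dataset(gfactor_cfg)


@pytest.fixture()
def tiny_dataset() -> LongitudinalDataset:
    """Six persons, hand-enterable scores, one missing cell."""
    rows = np.array(
        [
            [10.0, 12.0, 15.0, 5.0, 7.0, 8.0],
            [11.0, 14.0, 16.0, 6.0, 8.0, 10.0],
            [9.0, 11.0, 13.0, 4.0, 6.0, 7.0],
            [12.0, 15.0, 18.0, 7.0, 9.0, 11.0],
            [10.5, 13.0, np.nan, 5.5, 7.5, 9.0],
            [8.0, 10.0, 12.0, 3.0, 5.0, 6.0],
        ]
    )
    cols = [
        "vocabulary_T1",
        "vocabulary_T2",
        "vocabulary_T3",
        "reasoning_T1",
        "reasoning_T2",
        "reasoning_T3",
    ]
    return LongitudinalDataset(
        pd.DataFrame(rows, columns=cols), ("T1", "T2", "T3"), ("vocabulary", "reasoning")
    )
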