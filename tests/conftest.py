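import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dusgp.data_io import GenotypeTable, RunConfig, TrialTable
from dusgp.synthdata import simulate_panel, simulate_trials


@pytest.fixture
def worked_genotypes():
    """The 3-variety x 2-marker hand-computable panel."""
    return GenotypeTable(
        ["A", "B", "C"], [2, 2, 2],
        [[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]],
        pd.DataFrame({"marker": ["m1", "m2"], "chrom": ["1", "1"], "pos": [0, 1]}),
    )


@pytest.fixture
def small_panel():
    return simulate_panel(20, 80, seed=7)


@pytest.fixture
def small_trials(small_panel):
    trials, truth = simulate_trials(small_panel, n_environments=4,
                                    n_characteristics=2, seed=8)
    return trials


@pytest.fixture
def config():
    return RunConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
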