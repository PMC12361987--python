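import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

import methdx as m


@pytest.fixture(scope="session")
def small_cohort():
    """A planted cohort small enough for every unit test to share."""
    design = m.SynthDesign(n_cases=20, n_controls=15, n_sites=300, n_dms=10,
                           delta_target=0.3, mean_coverage=200,
                           detection_rate=0.9, conversion_efficiency=0.99, seed=7)
    counts, metadata, truth = m.simulate_cohort(design)
    return counts, metadata, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    counts, metadata, truth = small_cohort
    matrix = m.call_betas(counts, e=0.99)
    return matrix, metadata, truth


@pytest.fixture(scope="session")
def labels(small_matrix) -> pd.Series:
    return small_matrix[1]["class"]
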