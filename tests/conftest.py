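import logging

import numpy as np
import pandas as pd
import pytest

from circuc.datatypes import SampleTable
from circuc.synth import SimulationDesign, sample_table, simulate_feature_matrix

logging.getLogger("circuc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_planted():
    """Default study-scale planted dataset: 847 features, 20v20, 31 DE."""
    design = SimulationDesign(seed=11)
    expr, truth = simulate_feature_matrix(design)
    return design, expr, truth, sample_table(design)


@pytest.fixture(scope="session")
def small_planted():
    """Small, strongly separable dataset for fast classifier/consensus tests."""
    design = SimulationDesign(
        n_features=60, n_de=8, log2_fc_range=(1.5, 2.0),
        noise_sd_range=(0.4, 0.4), corr_blocks=(), seed=7,
    )
    expr, truth = simulate_feature_matrix(design)
    return design, expr, truth, sample_table(design)


@pytest.fixture()
def toy_meta():
    def make(n_cases, n_controls, fraction="platelet"):
        return SampleTable(pd.DataFrame({
            "sample_id": [f"p{i}" for i in range(n_cases)]
                         + [f"c{i}" for i in range(n_controls)],
            "group": ["case"] * n_cases + ["control"] * n_controls,
            "fraction": fraction,
        }))
    return make
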