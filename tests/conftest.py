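import numpy as np
import pandas as pd
import pytest

from slsift import datasets
from slsift.cohort import CohortSpec, PlantedPair, SynergyEffect, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def panel():
    return datasets.ladc_marker_panel()


@pytest.fixture(scope="session")
def synergy_rows():
    return datasets.ladc_synergy_rows()


@pytest.fixture(scope="session")
def demo_study():
    """A small planted study shared by integration-style tests."""
    spec = CohortSpec(
        n_patients=131,
        genes=["FEN1", "RAD54B", "BRCA1", "PARP1"],
        planted_pairs=[PlantedPair("FEN1", "RAD54B", "UU", 0.31, 2.0)],
        noise_sd=1.0,
        markers=datasets.ladc_marker_panel(),
        marker_rates=datasets.ladc_marker_rates(),
        synergy_effects=[SynergyEffect("FEN1(N)", "RAD54B(N)", "metastasis", 6.0)],
        seed=7,
    )
    return generate_study(spec)


def toy_matrix(values1, values2, genes=("G1", "G2")):
    """Patient x gene log2-ratio table from two value lists."""
    n = len(values1)
    return pd.DataFrame(
        {genes[0]: values1, genes[1]: values2},
        index=[f"P{i}" for i in range(n)],
    )
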