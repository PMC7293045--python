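import numpy as np
import pytest

from bremsc.datatypes import ModelParams, PairedCounts
from bremsc.simulator import scenario_config, simulate_bremsc


@pytest.fixture(scope="session")
def strong_data():
    """Well-separated simulated data set with ground truth (base condition)."""
    return simulate_bremsc(scenario_config(seed=11))


@pytest.fixture(scope="session")
def small_strong_data():
    """Smaller strongly separated data set for faster sampler tests."""
    return simulate_bremsc(
        scenario_config(cells_per_cluster=40, G=30, D=9, sigma_b=0.3, seed=7)
    )


@pytest.fixture
def toy_instance():
    """Hand-built 3-cell, 2-cluster instance for term-by-term oracles."""
    rna = np.array(
        [
            [5, 0, 2],
            [1, 3, 2],
            [0, 2, 1],
        ]
    )
    adt = np.array(
        [
            [4, 1, 2],
            [0, 3, 3],
        ]
    )
    data = PairedCounts(rna_counts=rna, adt_counts=adt)
    params = ModelParams(
        alpha_rna=np.array([[2.0, 1.0, 0.5], [0.5, 2.0, 1.5]]),
        alpha_adt=np.array([[3.0, 1.0], [1.0, 4.0]]),
        b=np.array([1.2, 0.8, 1.5]),
        sigma_b2=0.4,
        z=np.array([1, 2, 1]),
    )
    return data, params
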