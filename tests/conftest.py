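import numpy as np
import pytest

from masegc.io_core import LabelTable, Modality, OmicsMatrix
from masegc.synthetic_data import SimulationConfig, simulate_multiomics

SMALL_DIMS = {"exon": 60, "mrna": 40, "mirna": 20, "methylation": 30}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    return OmicsMatrix(
        Modality.MRNA,
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """52-sample, four-modality dataset with clear class signal."""
    cfg = SimulationConfig(
        n_samples_per_class=(40, 12), feature_dims=SMALL_DIMS, seed=3
    )
    return simulate_multiomics(cfg)


@pytest.fixture()
def labels4():
    return LabelTable(["s1", "s2", "s3", "s4"], np.array([1, 1, 0, 0]))
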