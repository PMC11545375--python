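import numpy as np
import pytest

from stenoselect.data import LabeledDataset, split_dataset
from stenoselect.synthetic import SyntheticSpec, make_feature_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """A 200-sample, 30-feature table with 5 planted informative columns."""
    ds, truth = make_feature_dataset(
        SyntheticSpec(n_samples=200, n_features=30, n_informative=5, effect_size=2.0, seed=42)
    )
    part = split_dataset(ds, (100, 60, 40), seed=42)
    return ds, part, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast 60-sample, 8-feature table for cheap wrapper evaluations."""
    ds, truth = make_feature_dataset(
        SyntheticSpec(n_samples=60, n_features=8, n_informative=2, effect_size=2.5, seed=7)
    )
    part = split_dataset(ds, (30, 15, 15), seed=7)
    return ds, part, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
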