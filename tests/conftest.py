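import numpy as np
import pandas as pd
import pytest

from qsarpipe import Dataset, SyntheticSpec, generate_dataset, load_published_fixture


def make_dataset(X, y, ids=None, columns=None, activity_name="pKi"):
    """Build a Dataset from plain arrays."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    ids = ids or [f"C{i+1}" for i in range(n)]
    columns = columns or [f"d{j+1}" for j in range(p)]
    frame = pd.DataFrame(X, index=pd.Index(ids, name="ID"), columns=columns)
    return Dataset(frame, pd.Series(np.asarray(y, dtype=float), index=frame.index,
                                    name=activity_name), activity_name)


@pytest.fixture
def tiny_dataset():
    return make_dataset([[0.0, 1.0], [5.0, 2.0], [10.0, 4.0]], [1.0, 2.0, 3.0])


@pytest.fixture
def fixture_model():
    return load_published_fixture()


@pytest.fixture
def noise_free():
    """50 compounds, 40 descriptors, exact 3-term linear truth."""
    spec = SyntheticSpec(
        n_compounds=50, n_descriptors=40, n_correlated_blocks=2, block_size=5,
        n_near_constant=4, noise_sd=0.0, true_support=(12, 20, 30),
        true_coefficients=(1.0, -0.5, 2.0), seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture
def noisy_small():
    """36 compounds, 12 descriptors, 3-term truth with mild noise."""
    spec = SyntheticSpec(
        n_compounds=36, n_descriptors=12, n_correlated_blocks=1, block_size=4,
        n_near_constant=2, noise_sd=0.2, true_support=(5, 7, 9),
        true_coefficients=(1.0, -0.8, 0.6), activity_range_target=None, seed=23,
    )
    return generate_dataset(spec)
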