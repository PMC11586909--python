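import numpy as np
import pytest

from fsgc.data import FunctionalDataset, ObservationKind


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_dataset(X, kind="continuous", levels=None, grid=None):
    """Dataset from an n x M matrix (NaN = missing)."""
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, X.shape[1])
    return FunctionalDataset.from_matrix(X, grid, ObservationKind(kind, levels))
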