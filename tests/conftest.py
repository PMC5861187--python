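import numpy as np
import pandas as pd
import pytest

from psyconn.connectivity import ConnectivityStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_stack_from_edges(edge_values: np.ndarray, n_rois: int, subject_ids=None) -> ConnectivityStack:
    """Build a ConnectivityStack whose upper-triangle edges equal the given
    (n_subjects, E) values — a controlled fixture for edge-wise inference."""
    n = edge_values.shape[0]
    iu, ju = np.triu_indices(n_rois, k=1)
    mats = np.zeros((n, n_rois, n_rois))
    mats[:, iu, ju] = edge_values
    mats[:, ju, iu] = edge_values
    mats[:, np.arange(n_rois), np.arange(n_rois)] = 1.0
    ids = subject_ids or [f"sub-{k + 1:03d}" for k in range(n)]
    return ConnectivityStack(subject_ids=ids, matrices=mats, roi_ids=list(range(1, n_rois + 1)))


@pytest.fixture
def scores_series():
    def _make(values, ids=None):
        ids = ids or [f"sub-{k + 1:03d}" for k in range(len(values))]
        return pd.Series(np.asarray(values, dtype=float), index=ids, name="param-01")

    return _make
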