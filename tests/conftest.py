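"""Shared fixtures: the three-slice worked example and a brute-force miner oracle."""

import itertools

import numpy as np
import pytest

from trictl.data_model import Feature, ThreeWayDataset
from trictl.mining import MiningParams, Tricluster, check_coherence

# Reference example: 3 objects x 3 features x 3 contexts; features y1 and
# y7 are categorical (integer-coded), y3 numeric.
B2 = [[1, 3.1, 5], [1, 2.8, 3], [3, 2.1, 10]]
B3 = [[2, 3.0, 3], [3, 2.8, 3], [3, 2.9, 9]]
B4 = [[3, 2.9, 3], [2, 2.9, 3], [3, 2.4, 8]]
P_ROWS = [[1, 2.22, 5], [1, 2.26, 7], [2, 2.35, 8]]  # object P over contexts C2..C4


def numeric_dataset(values: np.ndarray, missing=None) -> ThreeWayDataset:
    n, m, p = values.shape
    return ThreeWayDataset(
        [f"x{i}" for i in range(n)],
        [Feature(f"y{j}", "numeric") for j in range(m)],
        list(range(p)),
        values,
        np.zeros(values.shape, bool) if missing is None else missing,
    )


@pytest.fixture
def worked_example():
    values = np.stack([np.array(B, float) for B in (B2, B3, B4)], axis=2)
    cats = tuple(range(11))
    features = [
        Feature("y1", "categorical", cats),
        Feature("y3", "numeric"),
        Feature("y7", "categorical", cats),
    ]
    ds = ThreeWayDataset(
        ["x1", "x3", "x7"], features, [0, 1, 2], values, np.zeros(values.shape, bool)
    )
    tric = Tricluster((0, 1, 2), (0, 1, 2), (0, 1, 2))
    return ds, tric


def exhaustive_triclusters(values: np.ndarray, params: MiningParams):
    """Independent oracle: enumerate every maximal coherent contiguous tricluster.

    Brute force over all index-set triples (I, J, K-runs), coherence checked
    cell-by-cell via :func:`check_coherence`, maximality by containment over
    the coherent set.  Only feasible for tiny tensors.
    """
    n, m, p = values.shape
    ds = numeric_dataset(values)
    runs = [
        tuple(range(s, s + l))
        for l in range(params.mz, p + 1)
        for s in range(p - l + 1)
    ]
    coherent = []
    for j_size in range(params.my, m + 1):
        for J in itertools.combinations(range(m), j_size):
            for i_size in range(params.mx, n + 1):
                for I in itertools.combinations(range(n), i_size):
                    for K in runs:
                        t = Tricluster(I, J, K)
                        if check_coherence(t, ds, params)[0]:
                            coherent.append(t)
    return {
        (t.object_ids, t.feature_ids, t.context_ids)
        for t in coherent
        if not any(u != t and u.contains(t) for u in coherent)
    }


def as_key_set(triclusters):
    return {(t.object_ids, t.feature_ids, t.context_ids) for t in triclusters}
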