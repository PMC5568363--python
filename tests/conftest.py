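import itertools

import numpy as np
import pytest

import permtrial as pt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iid_normal_model():
    return pt.PopulationModel(
        categories=[
            pt.ResponseCategory("all", (pt.normal(0.0, 1.0), pt.normal(0.0, 1.0)), 1.0)
        ]
    )


def make_fixed_cohort(responses):
    """A cohort with fully deterministic, allocation-invariant responses."""
    y = np.asarray(responses, dtype=float)
    n = y.size
    return pt.Cohort(
        subject_id=np.arange(n, dtype=np.int64),
        cluster_id=np.arange(n, dtype=np.int64),
        category=np.zeros(n, dtype=object),
        y0=y.copy(),
        y1=y.copy(),
    )


@pytest.fixture
def fixed_cohort_factory():
    return make_fixed_cohort


def brute_force_balanced_splits(n):
    """All complete-balanced 0/1 assignment tuples for n subjects (oracle)."""
    rows = []
    ks = [n // 2] if n % 2 == 0 else [n // 2, n // 2 + 1]
    for k in ks:
        for combo in itertools.combinations(range(n), k):
            row = [0] * n
            for i in combo:
                row[i] = 1
            rows.append(tuple(row))
    return rows


@pytest.fixture
def balanced_splits_oracle():
    return brute_force_balanced_splits
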