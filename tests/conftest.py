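import numpy as np
import pytest

from oncotrees.data import BinaryAlterationMatrix

COHORT_COUNTS = {
    "PIK3CA": 51,
    "AKT2": 22,
    "KRAS": 25,
    "PTEN": 55,
    "ErbB2": 121,
    "CCND1": 153,
}


def make_matrix(values, events=None, ids=None) -> BinaryAlterationMatrix:
    values = np.asarray(values, dtype=np.int8)
    n, k = values.shape
    events = tuple(events) if events else tuple("ABCDEFGHIJ"[:k])
    ids = tuple(ids) if ids else tuple(f"s{i}" for i in range(n))
    return BinaryAlterationMatrix(ids, events, values)


def random_matrix(rng, n, k) -> BinaryAlterationMatrix:
    probs = rng.uniform(0.1, 0.9, size=k)
    values = (rng.random((n, k)) < probs).astype(np.int8)
    return make_matrix(values)


@pytest.fixture
def cohort_counts():
    return dict(COHORT_COUNTS)


@pytest.fixture
def cohort_fixture(cohort_counts):
    from oncotrees.simulate import fixture_from_counts

    return fixture_from_counts(963, cohort_counts, any_altered=342)
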