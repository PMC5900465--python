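import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def exhaustive_pam_cost(values, k):
    """Global optimum of the PAM objective by medoid-subset enumeration.

    Independent oracle: tries every subset of k distinct values as the
    medoid set and sums each point's distance to its nearest medoid.
    """
    values = np.asarray(values, dtype=float)
    best = np.inf
    for medoids in itertools.combinations(np.unique(values), k):
        m = np.asarray(medoids)
        cost = np.abs(values[:, None] - m[None, :]).min(axis=1).sum()
        best = min(best, cost)
    return best


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
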