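"""Shared fixtures and independent oracles for the test suite."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def enumerate_expected_nrad(counts, R):
    """Brute-force oracle for the MaxRank sub-sampling expectation.

    Enumerates every draw order of the individual pool, applies the stop
    rule literally (one individual at a time; the draw that would introduce
    the (R+1)-th distinct rank is rejected and sampling stops), normalizes
    each retained sub-sample, and averages.  Exponential cost: pools of at
    most ~8 individuals only.
    """
    pool = []
    for rank, c in enumerate(counts):
        pool.extend([rank] * c)
    total = np.zeros(R)
    n_orders = 0
    for perm in itertools.permutations(range(len(pool))):
        seen = set()
        kept = []
        for idx in perm:
            rank = pool[idx]
            if rank not in seen and len(seen) == R:
                break
            seen.add(rank)
            kept.append(rank)
        sub = sorted(Counter(kept).values(), reverse=True)
        vec = np.zeros(R)
        vec[: len(sub)] = np.asarray(sub) / sum(sub)
        total += vec
        n_orders += 1
    return total / n_orders


def permutation_prefix_sample(counts, R, rng):
    """Literal pool-permutation implementation of the stop-rule sub-sample.

    Independent of the package's arrival-time sampler; used to check that
    the two schemes agree in distribution.
    """
    pool = np.repeat(np.arange(len(counts)), counts)
    perm = rng.permutation(pool)
    if R < len(counts):
        _, first = np.unique(perm, return_index=True)
        stop = np.sort(first)[R]
        perm = perm[:stop]
    sub = np.bincount(perm)
    sub = sub[sub > 0]
    return np.sort(sub)[::-1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
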