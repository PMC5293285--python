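"""MaxRank normalization: stop rule, identity, oracles, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radnorm import (
    build_rad,
    choose_max_R,
    cutoff_normalize,
    downsample_individuals,
    maxrank_normalize,
    maxrank_normalize_set,
    maxrank_sample_once,
    relative_abundances,
)
from conftest import enumerate_expected_nrad, permutation_prefix_sample

rad_strategy = st.lists(
    st.integers(min_value=1, max_value=500), min_size=2, max_size=40
).map(lambda xs: build_rad(xs))


class TestSampleOnce:
    def test_full_richness_reproduces_rad_exactly(self, rng):
        rad = build_rad([4, 3, 1])
        for _ in range(20):
            assert maxrank_sample_once(rad, 3, rng).tolist() == [4, 3, 1]

    def test_r_above_richness_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds sample richness"):
            maxrank_sample_once(build_rad([3, 3]), 3, rng)

    def test_r_below_two_rejected(self, rng):
        with pytest.raises(ValueError, match="below 2"):
            maxrank_sample_once(build_rad([3, 3]), 1, rng)

    def test_exactly_r_ranks_sorted(self, rng):
        rad = build_rad([9, 6, 4, 2, 1])
        for R in (2, 3, 4):
            sub = maxrank_sample_once(rad, R, rng)
            assert sub.size == R
            assert np.all(np.diff(sub) <= 0)
            assert sub.sum() <= rad.n_individuals

    @pytest.mark.parametrize("counts,R", [([2, 1, 1], 2), ([4, 3, 1], 2), ([3, 2, 2, 1], 3)])
    def test_matches_enumeration_oracle(self, counts, R, rng):
        """Sampler mean equals exhaustive draw-order enumeration (<=8 individuals)."""
        exact = enumerate_expected_nrad(counts, R)
        rad = build_rad(counts)
        reps = np.empty((20000, R))
        for i in range(reps.shape[0]):
            sub = maxrank_sample_once(rad, R, rng)
            reps[i] = sub / sub.sum()
        se = reps.std(axis=0) / np.sqrt(reps.shape[0])
        assert np.all(np.abs(reps.mean(axis=0) - exact) <= 3 * np.maximum(se, 1e-12))

    def test_agrees_with_pool_permutation_scheme(self, rng):
        """Arrival-time sampler and literal pool permutation agree in mean."""
        rad = build_rad([50, 30, 12, 5, 2, 1])
        R = 4
        n = 4000
        ours = np.empty((n, R))
        literal = np.empty((n, R))
        for i in range(n):
            a = maxrank_sample_once(rad, R, rng)
            b = permutation_prefix_sample(rad.counts, R, rng)
            ours[i] = a / a.sum()
            literal[i] = b / b.sum()
        se = np.sqrt(ours.var(axis=0) / n + literal.var(axis=0) / n)
        assert np.all(np.abs(ours.mean(axis=0) - literal.mean(axis=0)) <= 4 * se)


class TestMaxrankNormalize:
    def test_identity_case(self):
        nrad = maxrank_normalize(build_rad([4, 3, 1]), 3, n_reps=7, seed=0)
        np.testing.assert_allclose(nrad.abundances, [0.5, 0.375, 0.125])
        np.testing.assert_allclose(nrad.ci_low, nrad.abundances)
        np.testing.assert_allclose(nrad.ci_high, nrad.abundances)

    def test_symmetric_pair(self):
        nrad = maxrank_normalize(build_rad([10, 10]), 2, n_reps=5, seed=1)
        np.testing.assert_allclose(nrad.abundances, [0.5, 0.5])

    def test_mean_matches_enumeration_oracle(self):
        exact = enumerate_expected_nrad([2, 1, 1], 2)
        nrad = maxrank_normalize(build_rad([2, 1, 1]), 2, n_reps=10000, seed=3)
        # per-rank MC standard error at 1e4 reps
        se = 0.5 / np.sqrt(10000)
        assert np.all(np.abs(nrad.abundances - exact) <= 3 * se)

    def test_reproducible_for_fixed_seed(self):
        rad = build_rad([40, 17, 9, 3, 2, 1, 1])
        a = maxrank_normalize(rad, 4, n_reps=25, seed=7)
        b = maxrank_normalize(rad, 4, n_reps=25, seed=7)
        np.testing.assert_array_equal(a.abundances, b.abundances)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)

    @given(rad=rad_strategy, data=st.data())
    @settings(max_examples=40)
    def test_conservation_and_ordering(self, rad, data):
        """Every NRAD sums to 1 and is non-increasing, with CIs bracketing."""
        R = data.draw(st.integers(min_value=2, max_value=rad.richness))
        seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
        nrad = maxrank_normalize(rad, R, n_reps=10, seed=seed)
        assert abs(nrad.abundances.sum() - 1.0) < 1e-9
        assert np.all(np.diff(nrad.abundances) <= 1e-15)
        assert np.all(nrad.ci_low <= nrad.abundances + 1e-12)
        assert np.all(nrad.ci_high >= nrad.abundances - 1e-12)

    @given(rad=rad_strategy, seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25)
    def test_identity_for_any_rad_and_seed(self, rad, seed):
        nrad = maxrank_normalize(rad, rad.richness, n_reps=5, seed=seed)
        np.testing.assert_array_equal(nrad.abundances, relative_abundances(rad))


class TestChooseMaxR:
    def test_minimum_richness(self):
        rads = [build_rad(np.arange(1, n + 1)) for n in (5, 3, 9)]
        assert choose_max_R(rads) == 3

    def test_singleton(self):
        assert choose_max_R([build_rad(np.arange(1, 8))]) == 7

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choose_max_R([])

    def test_normalize_set_uses_common_default_r(self):
        rads = [build_rad(np.arange(1, n + 1)) for n in (6, 4, 8)]
        nrads = maxrank_normalize_set(rads, n_reps=5, seed=0)
        assert {n.R for n in nrads} == {4}


class TestCutoffNormalize:
    @pytest.mark.parametrize(
        "counts, R, expected",
        [
            ([4, 3, 1], 2, [4 / 7, 3 / 7]),
            ([4, 3, 1], 3, [0.5, 0.375, 0.125]),
            ([1, 1, 1, 1], 2, [0.5, 0.5]),
        ],
    )
    def test_truncates_and_renormalizes(self, counts, R, expected):
        nrad = cutoff_normalize(build_rad(counts), R)
        np.testing.assert_allclose(nrad.abundances, expected)
        np.testing.assert_array_equal(nrad.ci_low, nrad.abundances)

    def test_precondition(self):
        with pytest.raises(ValueError, match="exceeds sample richness"):
            cutoff_normalize(build_rad([2, 1]), 3)


class TestDownsample:
    def test_target_richness_reached_exactly(self, rng):
        rad = build_rad(np.arange(1, 200))
        for target in (20, 50, 120):
            sub = downsample_individuals(rad, target, rng)
            assert sub.richness == target
            assert sub.n_individuals <= rad.n_individuals

    def test_target_at_or_above_richness_rejected(self, rng):
        rad = build_rad([4, 3, 1])
        with pytest.raises(ValueError, match="below sample richness"):
            downsample_individuals(rad, 3, rng)
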