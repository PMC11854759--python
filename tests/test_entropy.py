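"""Unit and property tests of the entropy core.

The refined composite measures are checked against independently coded
brute-force implementations (tests/_oracles.py), against their classic
single-scale counterparts at tau = 1, and against analytic limits.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mseeg import (
    EntropyConfig,
    UndefinedEntropyError,
    coarse_grain,
    entropy_curve,
    ordinal_patterns,
    permutation_entropy,
    permutation_frequencies,
    rcmpe,
    rcmse,
    sample_entropy,
    sample_entropy_counts,
)

from _oracles import (
    pattern_freq_bruteforce,
    rcmpe_bruteforce,
    rcmse_bruteforce,
    sampen_counts_bruteforce,
)


class TestCoarseGrain:
    @pytest.mark.parametrize("x, tau, expected", [
        ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
        ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),
        ([5, 1, 4, 4], 4, [3.5]),
    ])
    def test_block_means(self, x, tau, expected):
        np.testing.assert_allclose(coarse_grain(x, tau), expected)

    def test_identity_at_scale_one(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            coarse_grain([1, 2, 3], 0)
        with pytest.raises(ValueError):
            coarse_grain([1, 2, 3], 4)

    @given(st.integers(1, 7), st.integers(10, 60))
    @settings(max_examples=30, deadline=None)
    def test_length_is_floor_n_over_tau(self, tau, n):
        x = np.arange(n, dtype=float)
        assert len(coarse_grain(x, tau)) == n // tau


class TestSampleEntropyCounts:
    def test_constant_series_all_pairs_match(self):
        n_m, n_m1 = sample_entropy_counts(np.ones(20), m=2, r=0.5)
        assert n_m == n_m1 == 18 * 17      # ordered pairs of 18 templates
        assert sample_entropy(np.ones(20), 2, r=0.5) == 0.0

    @pytest.mark.parametrize("y", [
        [0, 100, 0, 100, 0],
        [1.0, 1.1, 0.9, 1.05, 1.0, 0.95, 1.2],
    ])
    def test_small_series_match_bruteforce(self, y):
        assert sample_entropy_counts(y, 2, 1.0) == \
            sampen_counts_bruteforce(y, 2, 1.0)

    def test_gaussian_series_match_bruteforce(self, rng):
        y = rng.standard_normal(1000)
        r = 0.15 * y.std()
        assert sample_entropy_counts(y, 2, r) == \
            sampen_counts_bruteforce(y, 2, r)

    def test_m1_counts_never_exceed_m_counts(self, rng):
        for _ in range(20):
            y = rng.standard_normal(rng.integers(20, 200))
            n_m, n_m1 = sample_entropy_counts(y, 2, 0.2)
            assert 0 <= n_m1 <= n_m

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy_counts([1.0, 2.0, 3.0], m=2, r=0.1)


class TestOrdinalPatterns:
    def test_pattern_count_is_m_factorial(self):
        for m in (3, 4, 5):
            assert len(ordinal_patterns(m)) == math.factorial(m)

    def test_monotone_series_single_ascending_pattern(self):
        freq = permutation_frequencies(np.arange(30.0), 4)
        assert freq[0] == 1.0 and freq[1:].sum() == 0.0

    def test_constant_series_stable_tie_pattern(self):
        freq = permutation_frequencies(np.zeros(30), 4)
        # ties broken by index order -> the ascending pattern
        assert freq[0] == 1.0

    def test_random_series_match_bruteforce(self, rng):
        y = rng.standard_normal(500)
        np.testing.assert_allclose(
            permutation_frequencies(y, 4),
            pattern_freq_bruteforce(y, 4), atol=1e-15)

    def test_delay_two_matches_bruteforce(self, rng):
        y = rng.standard_normal(200)
        np.testing.assert_allclose(
            permutation_frequencies(y, 3, delay=2),
            pattern_freq_bruteforce(y, 3, delay=2), atol=1e-15)

    def test_frequencies_sum_to_one(self, rng):
        y = rng.standard_normal(100)
        assert permutation_frequencies(y, 5).sum() == pytest.approx(1.0)


@pytest.mark.parametrize("variant", ["cumulative", "offset_composite"])
class TestRefinedComposite:
    def test_rcmse_matches_bruteforce(self, rng, variant):
        cfg = EntropyConfig(variant=variant)
        x = rng.standard_normal(600)
        for tau in (1, 2, 3, 5):
            assert rcmse(x, tau, cfg) == pytest.approx(
                rcmse_bruteforce(x, tau, variant=variant), abs=1e-12)

    def test_rcmpe_matches_bruteforce(self, rng, variant):
        cfg = EntropyConfig(variant=variant)
        x = rng.standard_normal(600)
        for tau in (1, 2, 3, 5):
            assert rcmpe(x, tau, cfg) == pytest.approx(
                rcmpe_bruteforce(x, tau, variant=variant), abs=1e-12)

    def test_reduce_to_classic_at_scale_one(self, rng, variant):
        cfg = EntropyConfig(variant=variant)
        x = rng.standard_normal(400)
        assert rcmse(x, 1, cfg) == sample_entropy(x, 2, 0.15 * x.std())
        assert rcmpe(x, 1, cfg) == permutation_entropy(x, 4)

    def test_constant_series_zero_rcmse(self, variant):
        cfg = EntropyConfig(variant=variant)
        assert rcmse(np.ones(100), 3, cfg) == 0.0

    def test_monotone_series_zero_rcmpe(self, variant):
        cfg = EntropyConfig(variant=variant)
        assert rcmpe(np.arange(200.0), 4, cfg) == 0.0

    def test_rcmpe_within_range(self, rng, variant):
        cfg = EntropyConfig(variant=variant)
        x = rng.standard_normal(500)
        for tau in (1, 2, 4):
            assert 0.0 <= rcmpe(x, tau, cfg) <= math.log(math.factorial(4))

    def test_undefined_matches_oracle_on_adversarial_inputs(self, rng,
                                                            variant):
        """UndefinedEntropy is raised exactly when the oracle counts are all
        zero, and never merely because one pooled scale has no matches."""
        cfg = EntropyConfig(variant=variant)
        cases = [np.array([0.0, 1e6, -1e6, 2e6, -3e6, 5e6, -8e6, 1.3e7]),
                 np.geomspace(1.0, 1e12, 9),
                 rng.standard_normal(12) * np.geomspace(1, 1e8, 12)]
        for x in cases:
            for tau in (1, 2):
                expected = rcmse_bruteforce(x, tau, variant=variant)
                if expected is None:
                    with pytest.raises(UndefinedEntropyError):
                        rcmse(x, tau, cfg)
                else:
                    assert rcmse(x, tau, cfg) == pytest.approx(expected,
                                                               abs=1e-12)


class TestAsymptotics:
    def test_uniform_noise_pe_approaches_ln24(self):
        x = np.random.default_rng(5).uniform(size=100_000)
        assert permutation_entropy(x, 4) == pytest.approx(math.log(24),
                                                          abs=0.01)

    def test_periodic_signal_pe_far_below_ln24(self):
        from mseeg import generate_reference_signal
        x = generate_reference_signal("periodic", 1000, seed=1)
        assert permutation_entropy(x, 4) < 0.5 * math.log(24)

    def test_white_noise_rcmse_above_periodic_at_every_scale(self):
        from mseeg import generate_reference_signal
        cfg = EntropyConfig()
        for rep in range(5):
            w, _ = entropy_curve(
                generate_reference_signal("white", 4096, seed=rep), cfg)
            p, _ = entropy_curve(
                generate_reference_signal("periodic", 4096, seed=rep), cfg)
            assert (w > p).all()


class TestEntropyCurve:
    def test_curve_matches_individual_calls(self, rng, cfg):
        x = rng.standard_normal(800)
        se, pe = entropy_curve(x, cfg)
        for tau in range(1, cfg.tau_max + 1):
            assert se[tau - 1] == rcmse(x, tau, cfg)
            assert pe[tau - 1] == rcmpe(x, tau, cfg)

    def test_curve_matches_calls_offset_variant(self, rng):
        cfg = EntropyConfig(variant="offset_composite", tau_max=5)
        x = rng.standard_normal(500)
        se, pe = entropy_curve(x, cfg)
        for tau in range(1, 6):
            assert se[tau - 1] == rcmse(x, tau, cfg)
            assert pe[tau - 1] == rcmpe(x, tau, cfg)

    def test_short_series_records_missing_scales(self):
        cfg = EntropyConfig(tau_max=10)
        x = np.random.default_rng(0).standard_normal(35)
        se, pe = entropy_curve(x, cfg)
        assert np.isnan(se[-1])            # 3 coarse samples: too short
        assert np.isnan(pe[-1])            # below the m_pe=4 pattern span
        assert np.isfinite(se[0])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EntropyConfig(m_pe=8)
        with pytest.raises(ValueError):
            EntropyConfig(r_coef=0.0)
        with pytest.raises(ValueError):
            EntropyConfig(variant="bogus")
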