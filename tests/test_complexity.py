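import numpy as np
import pytest

from hrvcc.complexity import (
    AllometricConfig,
    DFAConfig,
    MSEConfig,
    SampEnUndefinedError,
    aggregate,
    allometric_exponent,
    coarse_grain,
    dfa,
    multiscale_entropy,
    sample_entropy,
)
from hrvcc.synthetic import SeriesSpec, gen_series

from oracles import dfa_fluctuation_direct, sampen_bruteforce


class TestDFA:
    def test_white_noise_alpha_near_half(self):
        alphas = [
            dfa(gen_series(SeriesSpec(kind="white", n=9000, seed=s)).intervals).fit_exponent(4, 64)
            for s in range(1, 11)
        ]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("hurst", [0.5, 0.7, 0.9])
    def test_fgn_hurst_recovery(self, hurst):
        # estimator recovery across a seed ensemble
        alphas = [
            dfa(
                gen_series(SeriesSpec(kind="fgn", n=9000, hurst=hurst, seed=s)).intervals
            ).fit_exponent(4, 64)
            for s in range(1, 51)
        ]
        assert np.mean(alphas) == pytest.approx(hurst, abs=0.05)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            dfa(np.full(9000, 800.0))

    def test_fluctuation_curve_matches_direct_oracle(self, white_series):
        result = dfa(white_series)
        for n in (4, 16, 64):
            assert result.fluctuation_curve[n] == pytest.approx(
                dfa_fluctuation_direct(white_series, n), rel=1e-9
            )

    def test_alpha1_alpha2_are_range_fits(self, white_series):
        r = dfa(white_series)
        assert r.alpha1 == pytest.approx(r.fit_exponent(4, 11))
        assert r.alpha2 == pytest.approx(r.fit_exponent(12, 64))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DFAConfig(short_range=(4, 20), long_range=(12, 64))
        with pytest.raises(ValueError):
            DFAConfig(short_range=(2, 11), detrend_order=1)


class TestAggregate:
    def test_pairwise_sum(self):
        assert np.array_equal(aggregate(np.array([1.0, 2, 3, 4, 5, 6]), 2), [3, 7, 11])

    def test_level_one_identity(self):
        x = np.array([1.0, 2, 3])
        assert np.array_equal(aggregate(x, 1), x)

    def test_remainder_dropped(self):
        assert np.array_equal(aggregate(np.array([1.0, 2, 3, 4, 5]), 2), [3, 7])

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            aggregate(np.array([1.0, 2]), 0)


class TestAllometric:
    def test_white_noise_h_near_half(self):
        hs = [
            allometric_exponent(gen_series(SeriesSpec(kind="white", n=9000, seed=s)).intervals).h
            for s in range(1, 11)
        ]
        assert np.mean(hs) == pytest.approx(0.5, abs=0.03)

    def test_linear_ramp_h_near_one(self):
        ramp = np.arange(1, 9001, dtype=float)
        assert allometric_exponent(ramp).h == pytest.approx(1.0, abs=0.03)

    def test_fd_is_two_minus_h(self, white_series):
        r = allometric_exponent(white_series)
        assert r.fd + r.h == 2.0  # exact, by construction

    def test_level_means_grow_monotonically(self, white_series):
        r = allometric_exponent(white_series)
        means = [r.level_means[k] for k in sorted(r.level_means)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_constant_series_errors(self):
        with pytest.warns(UserWarning, match="zero SD"), pytest.raises(ValueError):
            allometric_exponent(np.full(2000, 800.0), AllometricConfig((1, 2, 4, 8)))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="points"):
            allometric_exponent(np.arange(1, 500, dtype=float))


class TestCoarseGrain:
    def test_window_means(self):
        assert np.array_equal(
            coarse_grain(np.array([1.0, 2, 3, 4, 5, 6]), 2), [1.5, 3.5, 5.5]
        )

    def test_scale_one_identity(self):
        x = np.array([3.0, 1, 4])
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_mean_linearity(self, rng):
        x = rng.uniform(0, 1, 1000)
        cg = coarse_grain(x, 7)
        n = (len(x) // 7) * 7
        assert cg.mean() == pytest.approx(x[:n].mean(), rel=1e-12)

    def test_scale_exceeding_length_errors(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(5, dtype=float), 6)


class TestSampleEntropy:
    def test_periodic_series_near_zero(self):
        x = np.tile([800.0, 900.0], 200)  # period 2 <= m: perfectly predictable
        assert sample_entropy(x, m=2, r_fraction=0.15) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(60, 200))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 3))
            r = float(rng.choice([0.1, 0.15, 0.2])) * x.std()
            assert sample_entropy(x, m=m, tolerance=r) == pytest.approx(
                sampen_bruteforce(x, m, r), abs=1e-12
            )

    def test_white_noise_more_irregular_than_ar1(self):
        white = gen_series(SeriesSpec(kind="white", n=3000, seed=1)).intervals
        smooth = gen_series(SeriesSpec(kind="ar1", n=3000, phi=0.95, seed=1)).intervals
        assert sample_entropy(white) > sample_entropy(smooth)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            sample_entropy(np.full(100, 1.0))

    def test_no_matches_flagged_not_zero(self):
        # widely spaced values with tiny tolerance: zero m-matches
        x = np.arange(50, dtype=float) ** 2
        with pytest.raises(SampEnUndefinedError):
            sample_entropy(x, m=2, tolerance=1e-9)


class TestMultiscaleEntropy:
    def test_white_noise_entropy_decreases_with_scale(self):
        x = gen_series(SeriesSpec(kind="white", n=9000, seed=9)).intervals
        r = multiscale_entropy(x)
        assert r.sampen_by_scale[1] > r.sampen_by_scale[20]

    def test_single_scale_equals_direct_sampen(self, rng):
        x = rng.standard_normal(600)
        r = multiscale_entropy(x, MSEConfig(scale_factors=(1,)))
        assert r.sampen_by_scale[1] == pytest.approx(sample_entropy(x), abs=1e-12)

    def test_tolerance_fixed_from_scale1_sd(self, rng):
        # at scale > 1 the fixed-r value differs from a per-scale-r one
        x = rng.standard_normal(4000)
        fixed = multiscale_entropy(x, MSEConfig(scale_factors=(1, 10)))
        per_scale = multiscale_entropy(x, MSEConfig(scale_factors=(1, 10), per_scale_r=True))
        assert fixed.sampen_by_scale[1] == per_scale.sampen_by_scale[1]
        assert fixed.sampen_by_scale[10] != per_scale.sampen_by_scale[10]

    def test_generative_irregularity_ordering_at_scale20(self):
        # cohorts generated with different irregularity keep their ordering:
        # white noise vs a deterministic 40-beat cycle (maximally regular)
        irregular = [
            multiscale_entropy(gen_series(SeriesSpec(kind="white", n=8000, seed=s)).intervals)
            for s in range(3)
        ]
        regular = [
            multiscale_entropy(
                gen_series(SeriesSpec(kind="periodic", n=8000, period=40, seed=s)).intervals
            )
            for s in range(3)
        ]
        mean_irr = np.mean([r.sampen_by_scale[20] for r in irregular])
        mean_reg = np.mean([r.sampen_by_scale[20] for r in regular])
        assert mean_irr > mean_reg

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            multiscale_entropy(np.random.default_rng(0).standard_normal(300))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MSEConfig(m=0)
        with pytest.raises(ValueError):
            MSEConfig(r=1.5)
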