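import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, norm

from electrome.descriptive import (
    acf,
    correlation_time,
    detect_undulation,
    dispersion,
    histogram,
    mean_voltage,
    prevalence_percent,
)
from electrome.io import Recording
from electrome.synthesis import gen_colored_noise, gen_undulation


def brute_force_acf(x, max_lag):
    """O(n·lag) direct-sum oracle for the biased ACF estimator."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc**2)
    return np.array(
        [np.sum(xc[: len(x) - k] * xc[k:]) / denom for k in range(max_lag + 1)]
    )


def ar1(phi, n, seed):
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestMeanAndDispersion:
    def test_constant_mean(self):
        assert mean_voltage(np.full(10, 5.0)) == 5.0

    def test_symmetric_mean_zero(self):
        assert mean_voltage(np.tile([1.0, -1.0], 50)) == 0.0

    def test_mean_matches_naive_sum(self, rng):
        x = rng.standard_normal(10_001)
        naive = sum(float(v) for v in x) / len(x)
        assert abs(mean_voltage(x) - naive) <= 1e-12 * max(1.0, abs(naive))

    def test_moments_match_direct_formula(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        m = x.mean()
        m2, m3, m4 = (np.mean((x - m) ** k) for k in (2, 3, 4))
        d = dispersion(x)
        assert d.skewness == pytest.approx(m3 / m2**1.5, rel=1e-12)
        assert d.kurtosis == pytest.approx(m4 / m2**2, rel=1e-12)

    def test_symmetric_series_zero_skewness(self):
        x = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert dispersion(x).skewness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_conventions(self):
        raws, excesses = [], []
        for s in range(10):
            x = np.random.default_rng(s).standard_normal(100_000)
            raws.append(dispersion(x, "raw").kurtosis)
            excesses.append(dispersion(x, "excess").kurtosis)
        assert abs(np.mean(raws) - 3.0) < 0.1
        assert abs(np.mean(excesses)) < 0.1

    def test_zero_variance_flagged(self):
        d = dispersion(np.full(10, 2.0))
        assert not d.defined
        assert np.isnan(d.skewness) and np.isnan(d.kurtosis)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_affine_invariance_of_shape_moments(self, shift, scale):
        x = np.random.default_rng(4).standard_normal(500) ** 3
        d0 = dispersion(x)
        d1 = dispersion(scale * x + shift)
        assert d1.skewness == pytest.approx(d0.skewness, abs=1e-9)
        assert d1.kurtosis == pytest.approx(d0.kurtosis, abs=1e-9)


class TestHistogram:
    def test_single_bin_collects_all(self):
        edges, counts = histogram(np.linspace(0, 1, 100), bins=1)
        assert counts.sum() == 100 and counts[0] == 100

    def test_counts_conserved(self, rng):
        x = rng.standard_normal(1234)
        _, counts = histogram(x, bins=31)
        assert counts.sum() == 1234

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            histogram(np.arange(10.0), bins=np.array([0.0, 2.0, 1.0]))

    def test_gaussian_passes_chi2_goodness_of_fit(self):
        x = np.random.default_rng(8).standard_normal(50_000)
        edges = np.linspace(-3.0, 3.0, 16)
        _, counts = histogram(x, bins=edges)
        probs = np.diff(norm.cdf(edges, loc=x.mean(), scale=x.std()))
        expected = probs * len(x)
        stat = np.sum((counts - expected) ** 2 / expected)
        crit = chi2.ppf(0.99, df=len(expected) - 1 - 2)
        assert stat < crit


class TestACF:
    def test_lag_zero_is_one(self, rng):
        res = acf(rng.standard_normal(500), max_lag=10)
        assert res.acf[0] == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self, rng):
        for n in (50, 137, 300):
            x = rng.standard_normal(n) ** 3
            res = acf(x, max_lag=min(30, n - 2))
            np.testing.assert_allclose(
                res.acf, brute_force_acf(x, min(30, n - 2)), atol=1e-9
            )

    def test_white_noise_within_large_sample_bound(self):
        x = np.random.default_rng(2).standard_normal(100_000)
        res = acf(x, max_lag=100)
        assert np.all(np.abs(res.acf[1:]) < 4 / np.sqrt(len(x)))

    def test_ar1_matches_closed_form(self):
        x = ar1(0.9, 100_000, seed=5)
        res = acf(x, max_lag=20)
        np.testing.assert_allclose(res.acf[1:], 0.9 ** np.arange(1, 21), atol=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            acf(np.full(100, 1.0), max_lag=5)


class TestCorrelationTime:
    def test_white_noise_integral_near_one(self):
        Ls = [
            correlation_time(
                acf(np.random.default_rng(s).standard_normal(100_000), max_lag=500)
            ).samples
            for s in range(5)
        ]
        assert abs(np.mean(Ls) - 1.0) < 0.3

    def test_ar1_integral_matches_geometric_sum(self):
        Ls = [
            correlation_time(acf(ar1(0.9, 100_000, seed=s), max_lag=2000)).samples
            for s in range(5)
        ]
        assert abs(np.mean(Ls) - 10.0) / 10.0 < 0.15

    def test_one_over_e_method(self):
        x = ar1(0.9, 100_000, seed=1)
        ct = correlation_time(acf(x, max_lag=100), method="one_over_e")
        # 0.9^k <= 1/e at k = 10 (0.9^10 = 0.349 < 0.368 fails at 9)
        assert ct.samples in (9.0, 10.0, 11.0)

    def test_monotone_acf_flags_lower_bound(self):
        res = acf(np.linspace(0, 1, 200) ** 2, max_lag=5)
        ct = correlation_time(res)
        assert ct.lower_bound

    def test_undulation_increases_L(self):
        base = gen_colored_noise(1.0, 2**14, seed=61)
        und = gen_undulation(base, amp=2.0, band=(0.002, 0.02), seed=62)
        L0 = correlation_time(acf(base, max_lag=2000)).samples
        L1 = correlation_time(acf(und, max_lag=2000)).samples
        assert L1 > L0


class TestUndulationReport:
    def test_prevalence_truncates_to_one_decimal(self):
        assert prevalence_percent(20, 23) == 86.9
        assert prevalence_percent([True] * 20 + [False] * 3) == 86.9
        assert prevalence_percent(1, 2) == 50.0

    def test_detector_flags_undulating_not_baseline(self):
        base = gen_colored_noise(1.0, 2**14, seed=71)
        und = gen_undulation(base, amp=2.0, band=(0.002, 0.02), seed=72)
        assert detect_undulation(und)
        assert not detect_undulation(base)
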