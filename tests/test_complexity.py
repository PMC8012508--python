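import numpy as np
import pytest
from scipy.stats import kendalltau

from electrome.complexity import (
    apen,
    coarse_grain,
    multiscale_entropy,
    pdf_tail_fit,
    sampen,
)
from electrome.synthesis import gen_brownian, gen_colored_noise


# ---------------------------------------------------------------------------
# brute-force oracles: direct double-loop implementations of the definitions


def brute_apen(x, m, r):
    x = np.asarray(x, dtype=float)

    def phi(mm):
        nm = len(x) - mm + 1
        templates = [x[i : i + mm] for i in range(nm)]
        total = 0.0
        for ti in templates:
            count = sum(
                1 for tj in templates if np.max(np.abs(ti - tj)) <= r
            )
            total += np.log(count / nm)
        return total / nm

    return phi(m) - phi(m + 1)


def brute_sampen(x, m, r):
    x = np.asarray(x, dtype=float)
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                b += 1
                if np.max(np.abs(x[i : i + m + 1] - x[j : j + m + 1])) <= r:
                    a += 1
    return -np.log(a / b)


class TestApEn:
    def test_constant_series_is_exactly_zero(self):
        assert apen(np.full(1000, 5.0), m=2, r=0.2) == 0.0

    @pytest.mark.parametrize("m", [1, 2])
    @pytest.mark.parametrize("n", [60, 150, 300])
    def test_matches_brute_force_oracle(self, m, n):
        x = np.random.default_rng(n + m).standard_normal(n)
        r = 0.2 * x.std()
        assert apen(x, m=m, r=r) == pytest.approx(brute_apen(x, m, r), abs=1e-12)

    def test_white_noise_more_irregular_than_sine(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(5000)
        t = np.arange(5000)
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * t / 50)  # equal variance
        a_noise = apen(noise, m=2, r=0.2 * noise.std())
        a_sine = apen(sine, m=2, r=0.2 * sine.std())
        assert a_noise > a_sine

    def test_affine_invariance_with_relative_tolerance(self):
        x = np.random.default_rng(5).standard_normal(400)
        a0 = apen(x, m=2, r_coef=0.2)
        a1 = apen(7.5 * x - 3.0, m=2, r_coef=0.2)
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apen(np.arange(100.0), m=2, r=0.0)


class TestSampEn:
    def test_constant_series_is_zero(self):
        assert sampen(np.full(200, 1.0), m=2, r=0.2) == 0.0

    @pytest.mark.parametrize("n", [80, 200, 300])
    def test_matches_brute_force_oracle(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        r = 0.25 * x.std()
        assert sampen(x, m=2, r=r) == pytest.approx(brute_sampen(x, 2, r), abs=1e-12)

    def test_no_matches_returns_nan_with_warning(self):
        x = np.geomspace(1.0, 1e6, 30)  # exploding series: no close templates
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(sampen(x, m=2, r=1e-9))

    def test_white_noise_exceeds_strongly_correlated_ar1(self):
        diffs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            noise = rng.standard_normal(2000)
            ar = np.empty(2000)
            eps = rng.standard_normal(2000)
            ar[0] = eps[0]
            for t in range(1, 2000):
                ar[t] = 0.95 * ar[t - 1] + eps[t]
            diffs.append(
                sampen(noise, m=2, r=0.2 * noise.std())
                - sampen(ar, m=2, r=0.2 * ar.std())
            )
        assert np.mean(diffs) > 0


class TestCoarseGrain:
    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_array_equal(coarse_grain([1.0, 3.0, 5.0, 7.0], 2), [2.0, 6.0])

    def test_variance_shrinks_like_one_over_s(self):
        x = np.random.default_rng(9).standard_normal(200_000)
        for s in (2, 5, 10):
            assert np.var(coarse_grain(x, s)) == pytest.approx(1.0 / s, rel=0.1)

    def test_scale_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(10.0), 11)


class TestMultiscaleEntropy:
    def test_constant_series_zero_at_every_scale(self):
        prof = multiscale_entropy(np.full(2000, 3.0), S=10)
        assert np.all(prof.values == 0.0)

    def test_white_noise_entropy_decreases_with_scale(self):
        rec = gen_colored_noise(0.0, 2**13, seed=81)
        prof = multiscale_entropy(rec, S=15)
        tau = kendalltau(prof.scales, prof.values).statistic
        assert tau < 0

    def test_brown_noise_entropy_rises_with_scale(self):
        rec = gen_brownian(2**13, seed=82)
        prof = multiscale_entropy(rec, S=15)
        assert prof.values[-1] > prof.values[0]

    def test_short_series_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            prof = multiscale_entropy(np.random.default_rng(1).standard_normal(500),
                                      S=50)
        assert prof.scales[-1] < 50

    def test_variant_sampen_supported(self):
        rec = gen_colored_noise(0.0, 2**11, seed=83)
        prof = multiscale_entropy(rec, S=3, variant="sampen")
        assert prof.variant == "sampen" and np.all(np.isfinite(prof.values))


class TestPdfTailFit:
    def test_exact_power_law_grid_recovered(self):
        # deterministic magnitudes laid out so the binned density is a
        # pure power law: x_i = inverse-CDF of a Pareto at equal ranks
        mu = 3.0
        u = (np.arange(1, 200_001) - 0.5) / 200_000
        mag = u ** (-1.0 / (mu - 1.0))  # survival-function inversion
        x = mag * np.tile([1.0, -1.0], 100_000)
        fit = pdf_tail_fit(x)
        assert fit.exponent == pytest.approx(mu, abs=0.05)
        assert fit.r2 > 0.999

    @pytest.mark.parametrize("mu", [2.0, 2.5, 3.0, 4.0])
    def test_pareto_exponent_recovery(self, mu):
        vals = []
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            mag = 1.0 + rng.pareto(mu - 1.0, 100_000)
            x = mag * rng.choice([-1.0, 1.0], 100_000)
            fit = pdf_tail_fit(x)
            vals.append(fit.exponent)
            assert fit.ok
        assert abs(np.mean(vals) - mu) < 0.3

    def test_gaussian_tail_fails_quality_gate(self):
        x = np.random.default_rng(3).standard_normal(100_000)
        assert not pdf_tail_fit(x).ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pdf_tail_fit(np.random.default_rng(0).standard_normal(50))
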