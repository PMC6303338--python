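import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from phylochron.age_compare import (
    ComparisonRecord,
    DifferenceDistribution,
    difference_distribution,
    hpd_interval,
    interval_probability,
    interval_probability_table,
    kde_fit,
    summarize_comparison,
)


def brute_force_hpd(draws, mass):
    """Independent oracle: exhaustive scan of all sorted windows."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        lo, hi = x[i], x[i + m - 1]
        if best is None or (hi - lo) < (best[1] - best[0]) - 0.0:
            best = (lo, hi)
    return best


class TestKdeFit:
    def test_standard_normal_density_at_zero(self, rng):
        est = kde_fit(rng.standard_normal(10_000))
        assert est.pdf(0.0)[0] == pytest.approx(norm.pdf(0.0), abs=0.02)

    def test_constant_sample_flagged(self):
        est = kde_fit(np.full(100, 5.0))
        assert est.is_degenerate and est.point == 5.0
        assert est.integrate(4.0, 6.0) == 1.0
        assert est.integrate(6.0, 7.0) == 0.0

    def test_integral_is_one(self, rng):
        samples = rng.normal(50.0, 7.0, size=2_000)
        est = kde_fit(samples)
        lo = samples.min() - 5 * est.bandwidth
        hi = samples.max() + 5 * est.bandwidth
        assert est.integrate(lo, hi) == pytest.approx(1.0, abs=1e-3)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            kde_fit(np.array([]))

    def test_scott_bandwidth(self, rng):
        samples = rng.standard_normal(1_000)
        est = kde_fit(samples, rule="scott")
        expected = samples.size ** (-1.0 / 5.0) * np.std(samples, ddof=1)
        assert est.bandwidth == pytest.approx(expected, rel=1e-9)

    def test_fixed_bandwidth(self, rng):
        est = kde_fit(rng.standard_normal(500), rule=2.5)
        assert est.bandwidth == pytest.approx(2.5, rel=1e-9)


class TestDifferenceDistribution:
    def test_same_samples_median_near_zero(self, rng):
        samples = rng.normal(100.0, 10.0, size=5_000)
        diff = difference_distribution(
            samples, samples, n=50_000, seed=3, label_a="x", label_b="y"
        )
        assert abs(np.median(diff.draws)) < 0.5

    def test_closed_form_mean(self, rng):
        a = rng.normal(484.0, 23.0, size=100_000)
        b = rng.normal(482.0, 3.0, size=100_000)
        diff = difference_distribution(a, b, n=100_000, seed=5, label_a="f", label_b="p")
        assert np.mean(diff.draws) == pytest.approx(2.0, abs=0.25)

    def test_closed_form_p_positive(self, rng):
        a = rng.normal(484.0, 23.0, size=100_000)
        b = rng.normal(482.0, 3.0, size=100_000)
        diff = difference_distribution(a, b, n=100_000, seed=5, label_a="f", label_b="p")
        expected = norm.cdf(2.0 / math.sqrt(23.0**2 + 3.0**2))
        assert np.mean(diff.draws > 0) == pytest.approx(expected, abs=0.01)

    def test_swap_negates_draws_exactly(self, rng):
        a = rng.normal(484.0, 23.0, size=2_000)
        b = rng.normal(482.0, 3.0, size=2_000)
        fwd = difference_distribution(a, b, n=10_000, seed=11, label_a="f", label_b="p")
        rev = difference_distribution(b, a, n=10_000, seed=11, label_a="p", label_b="f")
        assert np.array_equal(fwd.draws, -rev.draws)

    def test_fixed_seed_bit_identical(self, rng):
        a = rng.normal(10.0, 1.0, size=1_000)
        b = rng.normal(12.0, 1.0, size=1_000)
        d1 = difference_distribution(a, b, n=5_000, seed=7, label_a="x", label_b="y")
        d2 = difference_distribution(a, b, n=5_000, seed=7, label_a="x", label_b="y")
        assert np.array_equal(d1.draws, d2.draws)

    def test_degenerate_both_sides_flagged(self):
        a = np.full(100, 5.0)
        b = np.full(100, 3.0)
        diff = difference_distribution(a, b, n=1_000, seed=1, label_a="x", label_b="y")
        assert diff.is_degenerate
        assert np.all(diff.draws == 2.0)

    def test_empty_posterior_errors(self):
        with pytest.raises(ValueError):
            difference_distribution(np.array([]), np.array([1.0, 2.0]), n=10, seed=0)


@pytest.fixture(scope="module")
def std_normal_diff():
    rng = np.random.default_rng(42)
    draws = rng.standard_normal(100_000)
    return DifferenceDistribution(label_a="a", label_b="b", draws=draws, seed=42)


class TestIntervalProbability:
    def test_95_within_pm_196(self, std_normal_diff):
        p = interval_probability(std_normal_diff, 2 * 1.96)
        assert p == pytest.approx(0.95, abs=0.01)

    def test_zero_width_is_zero(self, std_normal_diff):
        assert interval_probability(std_normal_diff, 0.0) == 0.0

    def test_kde_vs_empirical_agree(self, std_normal_diff):
        for width in (1.0, 2.0, 4.0):
            p_kde = interval_probability(std_normal_diff, width, method="kde_integral")
            p_emp = interval_probability(std_normal_diff, width, method="empirical")
            assert abs(p_kde - p_emp) < 0.01

    def test_normal_sd10_range20(self):
        rng = np.random.default_rng(8)
        diff = DifferenceDistribution(
            label_a="a", label_b="b", draws=rng.normal(0.0, 10.0, 100_000), seed=8
        )
        # [-10, 10] = +/- 1 sd
        expected = norm.cdf(1.0) - norm.cdf(-1.0)
        assert interval_probability(diff, 20.0) == pytest.approx(expected, abs=0.01)

    def test_one_sided_semantics(self, std_normal_diff):
        p = interval_probability(std_normal_diff, 1.96, semantics="one_sided")
        assert p == pytest.approx(0.475, abs=0.01)

    def test_half_width_semantics(self, std_normal_diff):
        p = interval_probability(std_normal_diff, 1.96, semantics="half_width")
        assert p == pytest.approx(0.95, abs=0.01)


class TestIntervalTable:
    def test_point_mass_all_one(self):
        diff = DifferenceDistribution(
            label_a="a", label_b="b", draws=np.zeros(1_000), seed=0
        )
        table = interval_probability_table(diff)
        assert all(p == 1.0 for p in table.values())

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        diff = DifferenceDistribution(
            label_a="a", label_b="b", draws=rng.normal(0, 100.0, 50_000), seed=3
        )
        table = interval_probability_table(diff)
        values = [table[r] for r in sorted(table)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] < 1.0  # sd 100 >> 60/2

    @settings(max_examples=10, deadline=None)
    @given(
        mean=st.floats(min_value=-30, max_value=30),
        sd=st.floats(min_value=0.5, max_value=50.0),
    )
    def test_monotonicity_property(self, mean, sd):
        rng = np.random.default_rng(99)
        diff = DifferenceDistribution(
            label_a="a", label_b="b", draws=rng.normal(mean, sd, 5_000), seed=99
        )
        table = interval_probability_table(diff, method="empirical")
        values = [table[r] for r in sorted(table)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestHpdInterval:
    def test_uniform_grid_leftmost_window(self):
        draws = np.arange(1.0, 1001.0)
        lo, hi = hpd_interval(draws, mass=0.95)
        # ceil(0.95*1000)=950 points; every window has width 949; leftmost wins
        assert (lo, hi) == (1.0, 950.0)

    def test_all_identical_zero_width(self):
        lo, hi = hpd_interval(np.full(100, 7.0), mass=0.95)
        assert lo == hi == 7.0

    def test_exponential_analytic(self):
        rng = np.random.default_rng(17)
        draws = rng.exponential(1.0, size=100_000)
        lo, hi = hpd_interval(draws, mass=0.95)
        assert lo == pytest.approx(0.0, abs=0.005)
        assert hi == pytest.approx(-math.log(0.05), abs=0.1)

    def test_standard_normal_endpoints(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(100_000), mass=0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), mass=0.95)

    @pytest.mark.parametrize("dist", ["normal", "exponential", "lognormal", "uniform"])
    @pytest.mark.parametrize("mass", [0.5, 0.8, 0.95])
    def test_matches_brute_force(self, dist, mass):
        rng = np.random.default_rng(hash((dist, mass)) % 2**32)
        n = int(rng.integers(20, 2_000))
        draws = {
            "normal": lambda: rng.standard_normal(n),
            "exponential": lambda: rng.exponential(1.0, n),
            "lognormal": lambda: rng.lognormal(0.0, 1.0, n),
            "uniform": lambda: rng.uniform(-5, 5, n),
        }[dist]()
        assert hpd_interval(draws, mass) == pytest.approx(
            brute_force_hpd(draws, mass), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        mass=st.floats(min_value=0.1, max_value=0.99),
    )
    def test_brute_force_property(self, seed, mass):
        rng = np.random.default_rng(seed)
        draws = rng.lognormal(0.0, 1.5, size=int(rng.integers(20, 300)))
        assert hpd_interval(draws, mass) == brute_force_hpd(draws, mass)


class TestSummarizeComparison:
    def test_identical_posteriors(self, rng):
        samples = rng.normal(100.0, 5.0, size=20_000)
        rec = summarize_comparison(
            samples, samples, n_draws=50_000, seed=1, label_a="x", label_b="y"
        )
        assert rec.p_a_older == pytest.approx(0.5, abs=0.02)

    def test_shifted_pair_interval_probs(self, rng):
        a = rng.normal(150.0, 1.0, size=50_000)
        b = rng.normal(100.0, 1.0, size=50_000)
        rec = summarize_comparison(
            a, b, n_draws=100_000, seed=2, label_a="x", label_b="y"
        )
        # default width-centered semantics: mass near +50 is outside both
        # [-20, 20] and [-30, 30]
        assert rec.interval_probs[40.0] == pytest.approx(0.0, abs=1e-3)
        assert rec.interval_probs[60.0] == pytest.approx(0.0, abs=1e-3)
        assert rec.mean_diff == pytest.approx(50.0, abs=0.3)
        # half-width semantics: [-60, 60] captures the mass, [-40, 40] does not
        rec_hw = summarize_comparison(
            a, b, n_draws=100_000, seed=2, semantics="half_width",
            label_a="x", label_b="y",
        )
        assert rec_hw.interval_probs[60.0] == pytest.approx(1.0, abs=1e-3)
        assert rec_hw.interval_probs[40.0] == pytest.approx(0.0, abs=1e-3)

    def test_shifted_pair_hpd(self, rng):
        a = rng.normal(150.0, 1.0, size=50_000)
        b = rng.normal(100.0, 1.0, size=50_000)
        rec = summarize_comparison(
            a, b, n_draws=100_000, seed=2, label_a="x", label_b="y"
        )
        sd = math.sqrt(2.0)
        assert rec.hpd95[0] == pytest.approx(50.0 - 1.96 * sd, abs=0.1)
        assert rec.hpd95[1] == pytest.approx(50.0 + 1.96 * sd, abs=0.1)

    def test_hpd_mass_near_nominal(self, rng):
        a = rng.normal(120.0, 8.0, size=20_000)
        b = rng.normal(110.0, 6.0, size=20_000)
        rec = summarize_comparison(
            a, b, n_draws=50_000, seed=4, label_a="x", label_b="y"
        )
        lo, hi = rec.hpd95
        diff = difference_distribution(
            a, b, n=50_000, seed=4, label_a="x", label_b="y"
        )
        inside = np.mean((diff.draws >= lo) & (diff.draws <= hi))
        assert inside == pytest.approx(0.95, abs=2.0 / math.sqrt(50_000) + 1e-4)

    def test_as_row_columns(self, rng):
        samples = rng.normal(50.0, 3.0, size=5_000)
        rec = summarize_comparison(
            samples, samples, n_draws=10_000, seed=1, label_a="x", label_b="y"
        )
        row = rec.as_row()
        assert {"clade_a", "clade_b", "median_diff", "hpd_low", "p_within_60"} <= set(row)
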