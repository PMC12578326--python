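"""Parallelism statistics, regression, aggregation, rank-sum utility."""

import itertools

import numpy as np
import pytest

from parallign import (
    GroupSizeDistribution,
    NullModelConfig,
    aggregate,
    build_record,
    expected_counts,
    fit_regression,
    measured_parallelism,
    ms_weight_ratio,
    pms_ratio,
    rank_sum_compare,
    simulated_parallelism,
    weighted_parallelism_sum,
)
from conftest import exact_binom_pmf


def _dist(freq, n):
    return GroupSizeDistribution(freq=freq, n_branches=n)


class TestPerImageMetrics:
    def test_pm_examples(self):
        assert measured_parallelism(_dist({2: 1, 3: 1}, 10)) == pytest.approx(0.5)
        assert measured_parallelism(_dist({}, 7)) == 0.0
        assert measured_parallelism(_dist({8: 1}, 8)) == 1.0

    def test_pm_undefined_without_branches(self):
        with pytest.raises(ValueError):
            measured_parallelism(_dist({}, 0))

    def test_ps_integerized_and_analytic_at_61(self):
        ps_int = simulated_parallelism(expected_counts(61, NullModelConfig(mode="integerized")))
        assert ps_int == pytest.approx(45 / 61)
        ps_an = simulated_parallelism(expected_counts(61, NullModelConfig(mode="analytic")))
        assert ps_an == pytest.approx(1 - float(exact_binom_pmf(61, 1)), rel=1e-12)
        assert ps_an == pytest.approx(0.629, abs=0.001)

    def test_ps_degenerate_pair(self):
        ps = simulated_parallelism(expected_counts(2, NullModelConfig(mode="analytic")))
        assert ps == pytest.approx(0.5)  # lines = 2 * P(2) * 2 / 2 ... = 1 - P(1)

    def test_pms(self):
        assert pms_ratio(0.9, 0.6) == pytest.approx(1.5)
        assert pms_ratio(0.7, 0.7) == 1.0
        with pytest.raises(ValueError):
            pms_ratio(0.5, 0.0)

    def test_weighted_sum(self):
        assert weighted_parallelism_sum(_dist({2: 1, 3: 1}, 10)) == 13
        assert weighted_parallelism_sum(_dist({}, 5)) == 0
        null61 = expected_counts(61, NullModelConfig(mode="integerized"))
        assert weighted_parallelism_sum(null61) == 4 * 12 + 9 * 4 + 16 * 1 + 25 * 1  # 125

    def test_weighted_dominates_twice_lines(self):
        for freq in ({2: 3}, {2: 1, 5: 2}, {3: 4, 8: 1}):
            d = _dist(freq, 100)
            ws = weighted_parallelism_sum(d)
            assert ws >= 2 * d.parallel_lines
            if set(freq) == {2}:
                assert ws == 2 * d.parallel_lines

    def test_ms_ratio(self):
        assert ms_weight_ratio(125, 50) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            ms_weight_ratio(10, 0)


class TestRegression:
    def test_exact_line(self):
        fit = fit_regression([1, 2, 3], [0.66, 1.32, 1.98])
        assert fit.slope == pytest.approx(0.66)
        assert fit.r == pytest.approx(1.0)
        assert not fit.degenerate

    def test_constant_y_flagged(self):
        fit = fit_regression([1, 2, 3], [5, 5, 5])
        assert fit.slope == 0.0 and fit.r == 0.0 and fit.degenerate

    def test_constant_x_error(self):
        with pytest.raises(ValueError):
            fit_regression([2, 2, 2], [1, 2, 3])

    def test_recovers_planted_slope_under_noise(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(20, 250, 98)
        y = 0.66 * x + rng.normal(0, 1, 98)
        fit = fit_regression(x, y)
        assert fit.slope == pytest.approx(0.66, abs=0.05)


def _record(image_id, n, freq, mode="analytic"):
    measured = _dist(freq, n)
    return build_record(image_id, measured, expected_counts(n, NullModelConfig(mode=mode)))


class TestAggregate:
    def test_identical_records_have_zero_sd(self):
        recs = [_record(f"i{i}", 50, {2: 5, 3: 2}) for i in range(2)]
        summary = aggregate(recs)
        assert all(sd == 0.0 for sd in summary.metric_sds.values())

    def test_simulated_slope_matches_analytic_oracle(self):
        recs = [_record("a", 100, {2: 10}), _record("b", 200, {2: 20})]
        summary = aggregate(recs)
        # two-point slope from the exact analytic line totals
        l100 = 100 * (1 - float(exact_binom_pmf(100, 1)))
        l200 = 200 * (1 - float(exact_binom_pmf(200, 1)))
        assert summary.simulated_fit.slope == pytest.approx((l200 - l100) / 100, rel=1e-9)
        assert summary.simulated_fit.slope == pytest.approx(0.63, abs=0.01)

    def test_permutation_invariance(self):
        recs = [_record(f"i{i}", 40 + 17 * i, {2: 1 + i}) for i in range(5)]
        a = aggregate(recs)
        b = aggregate(recs[::-1])
        for key, val in a.metric_means.items():
            assert b.metric_means[key] == pytest.approx(val, nan_ok=True)
        assert a.measured_fit.slope == pytest.approx(b.measured_fit.slope)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            aggregate([_record("only", 30, {})])

    def test_blank_image_record_is_flagged(self):
        rec = build_record("blank", _dist({}, 0), None)
        assert np.isnan(rec.pm) and np.isnan(rec.ps) and np.isnan(rec.pms)


def _permutation_pvalue(a, b):
    """Exhaustive two-sided permutation distribution of the U statistic."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(sample_a, sample_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in sample_a for y in sample_b
        )

    observed = u_stat(a, b)
    mu = len(a) * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(sa, sb) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return observed, count / total


class TestRankSum:
    def test_identical_samples(self):
        u, p = rank_sum_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_fully_separated(self):
        u, p = rank_sum_compare(list(range(7)), list(range(10, 17)))
        assert u == 0.0
        assert p < 0.01

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.1, 2.3, 3.8, 4.1], [2.0, 2.9, 5.5, 6.1]),
            ([5, 6, 7, 8, 9], [1, 2, 3, 10]),
            ([1, 1, 2, 3, 5, 6, 7], [2, 2, 3, 4, 6, 9, 10]),  # ties
        ],
    )
    def test_against_exhaustive_permutation_oracle(self, a, b):
        u, p = rank_sum_compare(a, b)
        u_oracle, p_oracle = _permutation_pvalue(a, b)
        # U statistic is exact; p carries only normal-approximation error
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=0.05)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1, 2])
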