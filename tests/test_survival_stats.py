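import numpy as np
import pandas as pd
import pytest

from pairprog import (cox_multivariate, fisher_exact_2x2, freeman_halton,
                      km_estimate, km_median, mann_whitney, two_group_test)

from .oracles import enumerate_fisher_2x2


class TestKmEstimate:
    def test_all_censored_flat_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_two_events_closed_form(self):
        curve = km_estimate([1.0, 2.0], [1, 1])
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[0.0] == 1.0
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_negative_times_error(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])

    def test_monotone_non_increasing(self, rng):
        times = rng.exponential(2, 200)
        events = (rng.random(200) < 0.6).astype(int)
        curve = km_estimate(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.at_risk) <= 0)

    def test_exponential_limit_sup_norm(self):
        rng = np.random.default_rng(99)
        times = rng.exponential(1.0, 5000)
        curve = km_estimate(times, np.ones(5000))
        sup = np.max(np.abs(curve.survival - np.exp(-curve.times)))
        assert sup < 0.03

    def test_median(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(1.0, 4000)
        curve = km_estimate(times, np.ones(4000))
        assert km_median(curve) == pytest.approx(np.log(2), rel=0.1)


class TestTwoGroupTest:
    def test_null_labels(self, rng):
        times = rng.exponential(2, 300)
        events = (rng.random(300) < 0.7).astype(float)
        # same survival distribution in both groups
        labels = np.arange(300) % 2 == 0
        res = two_group_test(times, events, labels)
        assert res.wald_p > 0.05
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.35)

    def test_known_rate_ratio_recovery(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(1.0, 500)
            t1 = rng.exponential(1 / 3.0, 500)
            times = np.minimum(np.concatenate([t0, t1]), 2.0)
            events = (np.concatenate([t0, t1]) <= 2.0).astype(float)
            labels = np.repeat([False, True], 500)
            res = two_group_test(times, events, labels)
            if 2.5 <= res.hazard_ratio <= 3.6:
                hits += 1
        assert hits >= 29   # >= 95% expected; 30 seeded replicates

    def test_single_group_errors(self, rng):
        times = rng.exponential(2, 10)
        with pytest.raises(ValueError):
            two_group_test(times, np.ones(10), np.ones(10, bool))

    def test_order_and_time_scale_invariance(self, rng):
        times = rng.exponential(2, 100)
        events = (rng.random(100) < 0.7).astype(float)
        labels = rng.random(100) < 0.5
        base = two_group_test(times, events, labels)
        perm = rng.permutation(100)
        reordered = two_group_test(times[perm], events[perm], labels[perm])
        rescaled = two_group_test(times * 3.7, events, labels)
        assert reordered.wald_p == pytest.approx(base.wald_p, rel=1e-9)
        assert rescaled.wald_p == pytest.approx(base.wald_p, rel=1e-9)
        assert rescaled.hazard_ratio == pytest.approx(base.hazard_ratio,
                                                      rel=1e-9)

    def test_separation_falls_back_to_logrank(self):
        times = np.array([0.1, 0.2, 0.3, 5.0, 5.0, 5.0])
        events = np.array([1.0, 1, 1, 0, 0, 0])
        labels = np.array([True, True, True, False, False, False])
        res = two_group_test(times, events, labels)
        assert res.separated
        assert res.wald_p == pytest.approx(res.logrank_p)
        assert res.hazard_ratio > 1

    def test_ci_brackets_hr(self, rng):
        times = rng.exponential(2, 200)
        events = (rng.random(200) < 0.7).astype(float)
        labels = rng.random(200) < 0.4
        res = two_group_test(times, events, labels)
        assert res.ci[0] <= res.hazard_ratio <= res.ci[1]


def make_cox_frame(rng, n=400, beta=(1.0, 0.0)):
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    rate = 0.3 * np.exp(beta[0] * x1 + beta[1] * x2)
    t = rng.exponential(1 / rate)
    c = np.full(n, 4.0)
    return pd.DataFrame({"os_years": np.minimum(t, c),
                         "event": (t <= c).astype(int),
                         "x1": x1, "x2": x2})


class TestCoxMultivariate:
    def test_single_binary_covariate_matches_two_group(self, rng):
        times = rng.exponential(2, 150)
        events = (rng.random(150) < 0.7).astype(float)
        labels = rng.random(150) < 0.5
        table = pd.DataFrame({"os_years": times, "event": events,
                              "grp": labels.astype(float)})
        fit = cox_multivariate(table, ["grp"])
        res = two_group_test(times, events, labels)
        assert fit.terms.loc["grp", "wald_p"] == pytest.approx(res.wald_p,
                                                               abs=1e-6)
        assert fit.terms.loc["grp", "hazard_ratio"] == pytest.approx(
            res.hazard_ratio, rel=1e-5)

    def test_parameter_recovery(self):
        frame = make_cox_frame(np.random.default_rng(12), n=2000)
        fit = cox_multivariate(frame, ["x1", "x2"])
        assert fit.terms.loc["x1", "coef"] == pytest.approx(1.0, abs=0.15)
        assert fit.terms.loc["x2", "ci_low"] <= 1.0 <= fit.terms.loc["x2", "ci_high"]
        assert fit.n_used == 2000

    def test_listwise_deletion_reported(self, rng):
        frame = make_cox_frame(rng, n=100)
        frame.loc[frame.index[:20], "x2"] = np.nan
        fit = cox_multivariate(frame, ["x1", "x2"])
        assert fit.n_used == 80

    def test_constant_covariate_errors(self, rng):
        frame = make_cox_frame(rng, n=50)
        frame["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            cox_multivariate(frame, ["x1", "flat"])

    def test_collinear_covariates_named(self, rng):
        frame = make_cox_frame(rng, n=50)
        frame["x3"] = 2 * frame["x1"] + 1
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(frame, ["x1", "x2", "x3"])

    def test_too_few_rows(self, rng):
        frame = make_cox_frame(rng, n=5)
        with pytest.raises(ValueError, match="complete-case"):
            cox_multivariate(frame, ["x1"])


class TestFisherExact:
    def test_diagonal_table(self):
        p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)   # 2 / C(10,5)

    def test_flat_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_empty_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [1, 2]])

    def test_matches_enumeration_small_margins(self, rng):
        for _ in range(200):
            t = rng.integers(0, 7, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                enumerate_fisher_2x2(t), abs=1e-10)


class TestFreemanHalton:
    def test_2x2_delegates(self):
        assert freeman_halton([[5, 0], [0, 5]]) == pytest.approx(2 / 252,
                                                                 rel=1e-9)

    def test_independent_3x2_table_not_significant(self):
        p = freeman_halton([[5, 4], [4, 5], [5, 5]])
        assert p > 0.5

    def test_structured_3x3_significant(self):
        p = freeman_halton([[8, 0, 0], [0, 8, 0], [0, 0, 8]])
        assert p < 1e-4

    def test_monte_carlo_close_to_exact(self):
        table = [[4, 2, 3], [2, 5, 1], [3, 1, 4]]
        exact = freeman_halton(table)
        mc = freeman_halton(table, max_enumeration=1, n_mc=40000, seed=11)
        assert mc == pytest.approx(exact, abs=0.02)


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = np.arange(10.0)
        assert mann_whitney(x, x.copy()) >= 0.99

    def test_shifted_samples_significant(self, rng):
        x = rng.standard_normal(60)
        assert mann_whitney(x, x + 2.0) < 1e-6

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
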