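"""Bootstrap size-distribution comparison and adult-stage G-tests."""

import numpy as np
import pytest
from scipy import stats

from mudswim.distributions import (MIN_GTEST_COUNT, bootstrap_size_comparison,
                                   g_test_stages, observed_swimmer_proportions)
from mudswim.individuals import ADULT_STAGES, DEFAULT_SCHEME


class TestObservedProportions:
    def test_identical_nets_equal_single_net(self):
        net = [1.2, 1.2, 3.3, 5.1]
        p3, m, k = observed_swimmer_proportions([net, net, net])
        p1, _, _ = observed_swimmer_proportions([net])
        assert np.allclose(p3, p1)
        assert (m, k) == (12, 3)

    def test_two_disjoint_nets_average_to_half(self):
        pa, _, _ = observed_swimmer_proportions([[1.2, 1.3], [3.1, 3.2]])
        bins = DEFAULT_SCHEME.histogram_bins([1.2, 3.1])
        assert pa[bins[0]] == pytest.approx(0.5)
        assert pa[bins[1]] == pytest.approx(0.5)

    def test_mean_of_nets_differs_from_pooled_counts(self):
        # a large net dominated by one class vs a small net in another
        nets = [[1.2] * 90 + [3.2] * 10, [3.2]]
        p_mean, m, _ = observed_swimmer_proportions(nets)
        pooled = np.bincount(
            DEFAULT_SCHEME.histogram_bins([1.2] * 90 + [3.2] * 11),
            minlength=20) / 101
        b12 = DEFAULT_SCHEME.histogram_bins([1.2])[0]
        assert p_mean[b12] == pytest.approx(0.45)       # (0.9 + 0)/2
        assert pooled[b12] == pytest.approx(90 / 101)   # not the same quantity

    def test_no_usable_net_raises(self):
        with pytest.raises(ValueError, match="no net"):
            observed_swimmer_proportions([[]])


class TestBootstrapComparison:
    def test_below_threshold_reports_not_analysed(self, rng):
        res = bootstrap_size_comparison(
            rng.uniform(1, 10, size=99), [rng.uniform(1, 10, size=200)],
            rng=rng)
        assert not res.analysed
        assert "not analysed" in res.status
        assert res.table is None

    def test_small_b_rejected(self, rng):
        with pytest.raises(ValueError, match="B"):
            bootstrap_size_comparison(rng.uniform(1, 10, 200),
                                      [rng.uniform(1, 10, 200)], B=50)

    def test_trimmed_limits_match_independent_recomputation(self):
        """The same seeded draw stream, re-binned in the test, must give the
        26th and 975th sorted values as the limits at B=1000."""
        rng = np.random.default_rng(99)
        residents = rng.uniform(1, 10.5, size=300)
        swimmers = [rng.uniform(1, 10.5, size=150)]
        res = bootstrap_size_comparison(residents, swimmers, B=1000,
                                        rng=np.random.default_rng(7))
        # independent replication of the resampling with the same substream
        rng2 = np.random.default_rng(7)
        res_bins = DEFAULT_SCHEME.histogram_bins(residents)
        draws = rng2.choice(res_bins, size=(1000, 150), replace=True)
        boot = np.stack([np.bincount(d, minlength=20) for d in draws]) / 150
        boot.sort(axis=0)
        assert np.allclose(res.table["lower"].to_numpy(), boot[25])
        assert np.allclose(res.table["upper"].to_numpy(), boot[974])

    def test_degenerate_residents_flag_everything_else(self, rng):
        residents = np.full(200, 2.1)       # single occupied class
        swimmers = [np.full(100, 2.1).tolist() + [5.2] * 20]
        res = bootstrap_size_comparison(residents, swimmers, rng=rng)
        tab = res.table.set_index("size_class")
        assert tab.loc["2-2.5", "lower"] == 1.0
        assert tab.loc["2-2.5", "upper"] == 1.0
        assert tab.loc["5-5.5", "flag"] == "over"
        assert tab.loc["2-2.5", "flag"] == "under"

    def test_widening_trim_narrows_no_interval(self, rng):
        residents = rng.uniform(1, 10.5, size=400)
        swimmers = [rng.uniform(1, 10.5, size=60) for _ in range(3)]
        r25 = bootstrap_size_comparison(residents, swimmers,
                                        rng=np.random.default_rng(3), trim=25)
        r50 = bootstrap_size_comparison(residents, swimmers,
                                        rng=np.random.default_rng(3), trim=50)
        assert (r50.table["lower"] >= r25.table["lower"] - 1e-15).all()
        assert (r50.table["upper"] <= r25.table["upper"] + 1e-15).all()

    def test_seeded_bootstrap_is_reproducible(self, rng):
        residents = rng.uniform(1, 10.5, size=200)
        swimmers = [rng.uniform(1, 10.5, size=120)]
        a = bootstrap_size_comparison(residents, swimmers, seed=5)
        b = bootstrap_size_comparison(residents, swimmers, seed=5)
        assert a.table.equals(b.table)


class TestGTest:
    def test_identical_distributions_give_zero(self):
        counts = {"small male": 40, "large male": 30,
                  "small non-ovigerous female": 60,
                  "large non-ovigerous female": 20, "ovigerous female": 50}
        res = g_test_stages(counts, counts)
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 4

    def test_two_category_closed_form(self):
        exp = {"small male": 50, "ovigerous female": 50}
        obs = {"small male": 30, "ovigerous female": 70}
        res = g_test_stages(exp, obs, enforce_threshold=False)
        oracle = 2 * (30 * np.log(30 / 50) + 70 * np.log(70 / 50))
        assert res.g == pytest.approx(oracle, abs=1e-12)
        assert res.df == 1

    def test_matches_scipy_likelihood_ratio_oracle(self, rng):
        for _ in range(50):
            exp = {s: int(rng.integers(5, 200)) for s in ADULT_STAGES}
            obs = {s: int(rng.integers(5, 200)) for s in ADULT_STAGES}
            res = g_test_stages(exp, obs, enforce_threshold=False)
            e = np.array([exp[s] for s in ADULT_STAGES], dtype=float)
            o = np.array([obs[s] for s in ADULT_STAGES], dtype=float)
            g_ref, p_ref = stats.power_divergence(
                o, e / e.sum() * o.sum(), lambda_="log-likelihood")
            assert res.g == pytest.approx(g_ref, abs=1e-9)
            assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_zero_large_males_pool_into_small_males(self):
        exp = {"small male": 60, "large male": 0,
               "small non-ovigerous female": 80,
               "large non-ovigerous female": 40, "ovigerous female": 30}
        obs = {"small male": 50, "large male": 10,
               "small non-ovigerous female": 70,
               "large non-ovigerous female": 30, "ovigerous female": 20}
        res = g_test_stages(exp, obs)
        assert res.df == 3
        assert "large male -> small male" in res.pooled

    def test_zero_large_females_pool_into_ovigerous(self):
        exp = {"small male": 60, "large male": 20,
               "small non-ovigerous female": 80,
               "large non-ovigerous female": 0, "ovigerous female": 30}
        obs = {"small male": 50, "large male": 10,
               "small non-ovigerous female": 70,
               "large non-ovigerous female": 15, "ovigerous female": 20}
        res = g_test_stages(exp, obs)
        assert res.df == 3
        assert "large non-ovigerous female -> ovigerous female" in res.pooled

    def test_stage_empty_on_both_margins_is_dropped(self):
        exp = {"small male": 80, "large male": 0,
               "small non-ovigerous female": 80,
               "large non-ovigerous female": 40, "ovigerous female": 30}
        obs = {"small male": 70, "large male": 0,
               "small non-ovigerous female": 60,
               "large non-ovigerous female": 30, "ovigerous female": 25}
        res = g_test_stages(exp, obs)
        assert res.df == 3
        assert res.pooled == ()

    def test_threshold_is_strictly_greater_than_100(self):
        even = {s: 20 for s in ADULT_STAGES}             # total exactly 100
        assert not g_test_stages(even, even).analysed
        just_over = dict(even, **{"ovigerous female": 21})
        assert g_test_stages(just_over, just_over).analysed
        assert MIN_GTEST_COUNT == 100
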