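import itertools

import numpy as np
import pytest

from eaload import stats


class TestBurstiness:
    def test_regular_train_scores_minus_one(self):
        assert stats.burstiness([1.0] * 100) == -1.0

    def test_hand_evaluated_example(self):
        # intervals {1, 9}: mean 5, sample SD sqrt(32) -> (sd-5)/(sd+5)
        sd = np.sqrt(32.0)
        assert stats.burstiness([1.0, 9.0]) == pytest.approx((sd - 5) / (sd + 5))
        assert stats.burstiness([1.0, 9.0]) == pytest.approx(0.0617, abs=1e-4)

    def test_poissonian_intervals_score_near_zero(self, rng):
        b = stats.burstiness(rng.exponential(2.0, size=100_000))
        assert abs(b) < 0.01

    def test_range_property(self, rng):
        for _ in range(50):
            x = rng.uniform(0.01, 10, size=rng.integers(2, 50))
            b = stats.burstiness(x)
            assert -1.0 <= b < 1.0
            if np.allclose(x, x[0]):
                assert b == -1.0

    @pytest.mark.parametrize("bad", [[1.0], [], [1.0, -2.0], [1.0, 0.0]])
    def test_invalid_intervals_rejected(self, bad):
        with pytest.raises(ValueError):
            stats.burstiness(bad)


class TestSurrogates:
    def test_rate_adjustment_identity_without_dead_time(self):
        spec = stats.SurrogateSpec(rate_observed=0.4)
        assert stats.adjust_rate(spec) == 0.4

    def test_rate_adjustment_formula(self):
        spec = stats.SurrogateSpec(rate_observed=0.17, t_dead=0.0833)
        assert stats.adjust_rate(spec) == pytest.approx(
            0.17 / (1 - 0.17 * 0.0833)
        )
        assert stats.adjust_rate(spec) == pytest.approx(0.17244, abs=1e-5)

    def test_unrealizable_rate_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            stats.SurrogateSpec(rate_observed=0.4, t_dead=3.5)

    def test_spike_surrogate_rate_recovery(self):
        # dead time inserted after each event still reproduces the
        # observed rate thanks to the adjustment formula (checked at 1%)
        spec = stats.SurrogateSpec(rate_observed=0.8, t_dead=0.0833,
                                   duration=50_000.0)
        n = sum(
            stats.surrogate_events(spec, "spikes", rng=i).size
            for i in range(5)
        )
        rate = n / (5 * spec.duration)
        assert abs(rate - 0.8) / 0.8 < 0.01

    def test_burst_surrogate_rate_and_dead_time(self, rng):
        pool = tuple(rng.uniform(1.0, 10.0, size=200))
        mean_dur = float(np.mean(pool))
        spec = stats.SurrogateSpec(rate_observed=0.02, t_dead=3.5,
                                   t_event=mean_dur, duration=100_000.0,
                                   duration_pool=pool)
        counts = [stats.surrogate_events(spec, "bursts", rng=i).size
                  for i in range(5)]
        rate = sum(counts) / (5 * spec.duration)
        assert abs(rate - 0.02) / 0.02 < 0.01
        gaps = np.diff(stats.surrogate_events(spec, "bursts", rng=99))
        assert np.all(gaps >= 3.5)

    def test_burst_surrogates_need_duration_pool(self):
        spec = stats.SurrogateSpec(rate_observed=0.02, t_dead=3.5)
        with pytest.raises(ValueError, match="pool"):
            stats.surrogate_events(spec, "bursts", rng=0)


class TestPSurrogate:
    def test_tail_definitions_and_tie_rule(self):
        surr = [1.0, 2.0, 3.0, 3.0, 4.0]
        assert stats.p_surrogate(3.0, surr, "right") == pytest.approx(3 / 5)
        assert stats.p_surrogate(3.0, surr, "left") == pytest.approx(4 / 5)
        # complementarity: tails overlap on ties, so they sum to >= 1
        assert (stats.p_surrogate(3.0, surr, "right")
                + stats.p_surrogate(3.0, surr, "left")) >= 1.0

    def test_zero_fraction_reported_as_bound(self):
        surr = list(range(1000))
        p = stats.p_surrogate(2000.0, surr, "right")
        assert p == 0.0
        assert stats.format_p(p, 1000) == "< 0.001"

    def test_monotone_in_observed_statistic(self, rng):
        surr = rng.normal(size=500)
        ps = [stats.p_surrogate(x, surr, "right") for x in np.linspace(-3, 3, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPermutation:
    @staticmethod
    def _per_animal_mean_tau(values, labels):
        uniq = sorted(set(labels))
        means = np.array([values[labels == a].mean() for a in uniq])
        covar = np.arange(len(uniq), dtype=float)  # fixed per-animal covariate
        from scipy.stats import kendalltau
        return kendalltau(means, covar).statistic

    def test_requires_two_animals(self):
        with pytest.raises(ValueError, match="2 animals"):
            stats.permute_animals([1, 2], ["a", "a"], lambda v, l: 0.0)

    def test_planted_association_detected(self, rng):
        # animal-level means strongly ordered along the covariate
        labels = np.repeat(np.arange(6), 20)
        values = labels * 2.0 + rng.normal(0, 0.5, size=labels.size)
        hits = 0
        for rep in range(10):
            _, p, _ = stats.permute_animals(
                values, labels, self._per_animal_mean_tau,
                n_perm=200, tail="right", rng=rep,
            )
            hits += p < 0.05
        assert hits >= 9

    def test_label_invariant_statistic_never_significant(self, rng):
        labels = np.repeat(np.arange(4), 10)
        values = rng.normal(size=labels.size)
        grand_mean = lambda v, l: float(np.mean(v))
        _, p, _ = stats.permute_animals(values, labels, grand_mean,
                                        n_perm=200, rng=0)
        assert p > 0.5  # statistic unchanged up to float summation order


def brute_force_tau_b(x, y):
    """Tie-corrected Kendall tau from explicit pair concordance counts."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestCorrelation:
    def test_perfect_monotone_relationships(self):
        x = np.arange(10.0)
        assert stats.kendall_tau(x, 2 * x + 1).tau == pytest.approx(1.0)
        assert stats.kendall_tau(x, -x).tau == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=8).astype(float)  # ties likely
            y = rng.integers(0, 6, size=8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = stats.kendall_tau(x, y)
            assert res.tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.kendall_tau([1, 1, 1], [1, 2, 3])


def brute_force_theil_sen(x, y):
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[j] != x[i]
    ]
    slope = float(np.median(slopes))
    return slope, float(np.median(np.asarray(y) - slope * np.asarray(x)))


class TestTheilSen:
    def test_collinear_points_recovered_exactly(self):
        x = np.arange(10.0)
        slope, intercept = stats.theil_sen(x, 3.0 * x - 2.0)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(-2.0)

    def test_robust_to_gross_outlier(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        y[7] = 500.0
        slope, _ = stats.theil_sen(x, y)
        assert slope == pytest.approx(2.0, abs=1e-9)
        # ordinary least squares is dragged away by the same outlier
        ols = np.polyfit(x, y, 1)[0]
        assert abs(ols - 2.0) > 1.0

    def test_matches_brute_force_on_small_samples(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 10, size=9)
            y = rng.uniform(0, 10, size=9)
            got = stats.theil_sen(x, y)
            want = brute_force_theil_sen(x, y)
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])

    def test_two_points_is_ordinary_slope(self):
        slope, intercept = stats.theil_sen([0.0, 2.0], [1.0, 5.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            stats.theil_sen([1.0, 1.0], [0.0, 1.0])


class TestSurvival:
    def test_product_limit_hand_computed(self):
        times, surv = stats.km_survival([1.0, 2.0, 3.0, 4.0])
        lookup = dict(zip(times, surv))
        assert lookup[1.0] == pytest.approx(0.75)
        assert lookup[2.0] == pytest.approx(0.50)
        assert lookup[3.0] == pytest.approx(0.25)
        assert lookup[4.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        times, surv = stats.km_survival([5.0, 5.0, 5.0], censored=[1, 1, 1])
        assert np.all(surv == 1.0)

    def test_uncensored_equals_empirical_survival(self, rng):
        d = rng.exponential(10.0, size=50)
        times, surv = stats.km_survival(d)
        for t, s in zip(times[1:], surv[1:]):
            assert s == pytest.approx(np.mean(d > t))


class TestGroupTests:
    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=40)
        _, p = stats.kruskal_wallis(g, g.copy())
        assert p > 0.9

    def test_bonferroni_definition(self):
        np.testing.assert_allclose(
            stats.bonferroni([0.01, 0.2, 0.5]), [0.03, 0.6, 1.0]
        )

    def test_shifted_groups_detected_pairwise(self, rng):
        groups = {
            "a": rng.normal(0, 1, 200),
            "b": rng.normal(2, 1, 200),
            "c": rng.normal(4, 1, 200),
        }
        ps = stats.mann_whitney_pairs(groups)
        assert all(p < 0.001 for p in ps.values())


class TestUniformPlacement:
    def test_equal_bin_counts_give_p_one(self):
        pos = np.concatenate([np.full(5, (i + 0.5) / 10) for i in range(10)])
        chi2, p = stats.uniform_placement_test(pos)
        assert chi2 == 0.0 and p == 1.0

    def test_extreme_departure_detected(self):
        _, p = stats.uniform_placement_test(np.full(1000, 0.05))
        assert p < 1e-6

    def test_null_calibration(self, rng):
        ps = [stats.uniform_placement_test(rng.uniform(size=2631))[1]
              for _ in range(40)]
        # under the null the p values are roughly uniform
        assert np.mean(np.asarray(ps) < 0.5) == pytest.approx(0.5, abs=0.25)
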