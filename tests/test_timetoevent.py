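"""Turnbull NPMLE, quantiles, Wilcoxon scores and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germscreen.data import DishCounts, InspectionSchedule
from germscreen.timetoevent import (
    SeedIntervals,
    bootstrap_quantile_se,
    cdf_at,
    counts_to_intervals,
    fit_npmle,
    permutation_test,
    quantile_time,
    t50_germinated,
    turnbull_intervals,
    wilcoxon_scores,
)

from conftest import brute_force_loglik, random_interval_instance


def make_intervals(pairs, group="g", dish="d"):
    left, right = zip(*pairs)
    n = len(pairs)
    groups = [group] * n if isinstance(group, str) else group
    dishes = [dish] * n if isinstance(dish, str) else dish
    return SeedIntervals(np.array(left, float), np.array(right, float), groups, dishes)


class TestCountsToIntervals:
    def test_worked_dish_expansion(self, worked_dish, schedule):
        iv = counts_to_intervals(worked_dish, schedule)
        assert iv.n == 50
        pairs = list(zip(iv.left.tolist(), iv.right.tolist()))
        assert pairs.count((0.0, 1.0)) == 10
        assert pairs.count((1.0, 2.0)) == 20
        assert pairs.count((2.0, 3.0)) == 5
        assert pairs.count((6.0, np.inf)) == 15

    def test_all_germinated_day_one(self, schedule):
        dish = DishCounts("A", 0.0, "r1", 50, {1: 50, 2: 0, 3: 0, 6: 0})
        iv = counts_to_intervals(dish, schedule)
        assert np.all(iv.left == 0) and np.all(iv.right == 1)

    def test_none_germinated(self, schedule):
        dish = DishCounts("A", 0.0, "r1", 50, {1: 0, 2: 0, 3: 0, 6: 0})
        iv = counts_to_intervals(dish, schedule)
        assert np.all(iv.left == 6) and np.all(np.isinf(iv.right))


class TestTurnbullIntervals:
    def test_overlap_collapses_to_intersection(self):
        data = make_intervals([(0, 2), (0, 2), (1, 3), (1, 3)])
        np.testing.assert_array_equal(turnbull_intervals(data), [[1, 2]])

    def test_disjoint_intervals_kept(self):
        data = make_intervals([(0, 1), (1, 2)])
        np.testing.assert_array_equal(turnbull_intervals(data), [[0, 1], [1, 2]])

    def test_single_right_censored_seed(self):
        data = make_intervals([(6, np.inf)])
        ivals = turnbull_intervals(data)
        assert ivals.shape == (1, 2)
        assert ivals[0, 0] == 6 and np.isinf(ivals[0, 1])


class TestFitNPMLE:
    def test_aligned_intervals_give_empirical_proportions(self, worked_dish, schedule):
        fit = fit_npmle(counts_to_intervals(worked_dish, schedule))
        np.testing.assert_allclose(fit.masses, [0.2, 0.4, 0.1, 0.3], atol=1e-12)
        assert fit.converged

    def test_overlap_example_concentrates_mass(self):
        fit = fit_npmle(make_intervals([(0, 2), (0, 2), (1, 3), (1, 3)]))
        np.testing.assert_allclose(fit.masses, [1.0], atol=1e-12)
        assert fit.loglik == pytest.approx(0.0, abs=1e-12)

    def test_single_seed_identity(self):
        fit = fit_npmle(make_intervals([(0, 1)]))
        np.testing.assert_allclose(fit.masses, [1.0])

    def test_nonconvergence_is_flagged(self):
        # asymmetric overlap converges only geometrically (MLE w = 2/3)
        data = make_intervals([(0, 1), (0, 1), (0, 2), (1, 2)])
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_npmle(data, tol=1e-12, max_iter=2)
        assert not fit.converged

    def test_em_loglik_is_monotone_in_iterations(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = None
            while data is None:
                data = random_interval_instance(rng)
            lls = []
            for k in range(1, 12):
                with np.errstate(all="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = fit_npmle(data, tol=0.0, max_iter=k)
                lls.append(fit.loglik)
            assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_matches_bruteforce_grid_on_random_instances(self):
        """EM attains the global optimum (concave objective, grid oracle)."""
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 40:
            data = random_interval_instance(rng)
            if data is None:
                continue
            fit = fit_npmle(data)
            grid = brute_force_loglik(data, step=0.01)
            assert fit.loglik >= grid - 1e-6
            assert fit.loglik - grid <= 0.2
            checked += 1

    def test_reduces_to_kaplan_meier(self):
        """With exact events and right censoring the NPMLE is Kaplan-Meier."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        times = rng.integers(1, 6, size=40).astype(float)
        censored = rng.random(40) < 0.3
        # exact events encoded as (t - 0.5, t]; censored as (t, inf)
        left = np.where(censored, times, times - 0.5)
        right = np.where(censored, np.inf, times)
        fit = fit_npmle(make_intervals(list(zip(left, right))))
        km = lifelines.KaplanMeierFitter().fit(times, event_observed=~censored)
        for t in np.unique(times[~censored]):
            ours = cdf_at(fit, t).prob
            theirs = 1.0 - float(km.survival_function_at_times(t).iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-8)


class TestCdf:
    def test_known_values_and_normalization(self, worked_dish, schedule):
        fit = fit_npmle(counts_to_intervals(worked_dish, schedule))
        assert cdf_at(fit, 0).prob == 0.0
        assert cdf_at(fit, 2).prob == pytest.approx(0.6)
        assert cdf_at(fit, np.inf).prob == 1.0
        assert cdf_at(fit, 4.5).prob == pytest.approx(0.7)  # plateau after day 3

    def test_indeterminate_inside_turnbull_interval(self, worked_dish, schedule):
        fit = fit_npmle(counts_to_intervals(worked_dish, schedule))
        assert cdf_at(fit, 1.5).indeterminate
        assert not cdf_at(fit, 4.5).indeterminate

    def test_cdf_is_nondecreasing(self, worked_dish, schedule):
        fit = fit_npmle(counts_to_intervals(worked_dish, schedule))
        ts = np.linspace(0, 10, 101)
        vals = [cdf_at(fit, t).prob for t in ts]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestQuantiles:
    def test_worked_interpolation(self, worked_dish, schedule):
        fit = fit_npmle(counts_to_intervals(worked_dish, schedule))
        assert quantile_time(fit, 0.5).time == pytest.approx(1.75)

    def test_undefined_when_germination_too_low(self, schedule):
        dish = DishCounts("A", 0.0, "r1", 50, {1: 10, 2: 10, 3: 0, 6: 0})
        fit = fit_npmle(counts_to_intervals(dish, schedule))
        est = quantile_time(fit, 0.5)
        assert not est.defined

    def test_t50_on_germinated_scale(self, schedule):
        # 20 of 50 germinated: target is F = 0.2; crossing inside (0,1]
        dish = DishCounts("A", 0.0, "r1", 50, {1: 10, 2: 10, 3: 0, 6: 0})
        fit = fit_npmle(counts_to_intervals(dish, schedule))
        assert t50_germinated(fit).time == pytest.approx(1.0)

    @given(p=st.floats(0.05, 0.65))
    @settings(max_examples=25, deadline=None)
    def test_quantile_nondecreasing_in_p(self, p):
        dish = DishCounts("A", 0.0, "r1", 50, {1: 10, 2: 20, 3: 5, 6: 0}, 0)
        sched = InspectionSchedule((1, 2, 3, 6))
        fit = fit_npmle(counts_to_intervals(dish, sched))
        lo = quantile_time(fit, p)
        hi = quantile_time(fit, min(p + 0.05, 0.69))
        assert hi.time >= lo.time - 1e-12

    def test_time_shift_equivariance(self, worked_dish):
        base = InspectionSchedule((1, 2, 3, 6))
        shift = 2.0
        shifted_sched = InspectionSchedule(tuple(t + shift for t in base.times))
        shifted_dish = DishCounts(
            "A", 0.0, "r1", 50,
            {d + shift: n for d, n in worked_dish.new_germ.items()},
            worked_dish.n_abnormal,
        )
        f0 = fit_npmle(counts_to_intervals(worked_dish, base))
        f1 = fit_npmle(counts_to_intervals(shifted_dish, shifted_sched))
        t0 = quantile_time(f0, 0.5).time
        t1 = quantile_time(f1, 0.5).time
        # the first interval opens at sowing (0), not at the shifted origin,
        # so interpolation inside it stretches; compare beyond it
        t0b = quantile_time(f0, 0.65).time
        t1b = quantile_time(f1, 0.65).time
        assert t1b - t0b == pytest.approx(shift, abs=1e-9)


class TestBootstrapSE:
    def test_degenerate_data_gives_zero_se(self):
        data = make_intervals([(0, 1)] * 30)
        est = bootstrap_quantile_se(data, n_boot=50, seed=1)
        assert est.se == pytest.approx(0.0)

    def test_reproducible_given_seed(self, worked_dish, schedule):
        data = counts_to_intervals(worked_dish, schedule)
        a = bootstrap_quantile_se(data, n_boot=60, seed=42)
        b = bootstrap_quantile_se(data, n_boot=60, seed=42)
        assert a.se == b.se and a.time == b.time

    def test_se_tracks_monte_carlo_sd(self):
        """Bootstrap SE approximates the sampling sd of T50 over fresh data."""
        from germscreen.synth import ArchetypeParams, simulate_dish
        from germscreen.timetoevent import SeedIntervals

        params = ArchetypeParams(
            name="T", mu0=np.log(1.2), sigma=0.5, delta=1.0, pi0=0.95, rho=1.0,
            alpha0=0.0, alpha_salt=0.0,
            length_means=(1, 1, 1), length_sti=(1, 1, 1), tau=0.0,
        )
        sched = InspectionSchedule((1, 2, 3, 6))

        def one_dataset(rng):
            dishes = [
                simulate_dish(params, 0.0, sched, 50, rng, replicate=f"r{i}")
                for i in range(3)
            ]
            return SeedIntervals.concat(
                [counts_to_intervals(d, sched, group="g") for d in dishes]
            )

        rng = np.random.default_rng(9)
        mc = [
            t50_germinated(fit_npmle(one_dataset(rng))).time for _ in range(200)
        ]
        mc_sd = np.std(mc, ddof=1)
        est = bootstrap_quantile_se(one_dataset(np.random.default_rng(10)),
                                    n_boot=300, seed=11, relative=True)
        assert est.se == pytest.approx(mc_sd, rel=0.30)


class TestWilcoxonScores:
    def test_two_group_hand_example(self):
        data = make_intervals(
            [(0, 1)] * 10 + [(1, 2)] * 10,
            group=["A"] * 10 + ["B"] * 10,
            dish=["a1"] * 5 + ["a2"] * 5 + ["b1"] * 5 + ["b2"] * 5,
        )
        comp = wilcoxon_scores(data)
        assert comp.group_scores["A"] == pytest.approx(5.0)
        assert comp.group_scores["B"] == pytest.approx(-5.0)

    def test_scores_sum_to_zero_across_groups(self):
        from germscreen.synth import simulate_gradient
        from germscreen.timetoevent import panel_to_intervals

        panel, _ = simulate_gradient(rng_seed=2)
        comp = wilcoxon_scores(panel_to_intervals(panel))
        assert sum(comp.group_scores.values()) == pytest.approx(0.0, abs=1e-6)

    def test_single_group_rejected(self):
        data = make_intervals([(0, 1)] * 4)
        with pytest.raises(ValueError, match="two groups"):
            wilcoxon_scores(data)


class TestPermutationTest:
    def _separated(self):
        return make_intervals(
            [(0, 1)] * 20 + [(2, 3)] * 20,
            group=["A"] * 20 + ["B"] * 20,
            dish=[f"a{i % 4}" for i in range(20)] + [f"b{i % 4}" for i in range(20)],
        )

    def test_complete_separation_attains_minimum_p(self):
        res = permutation_test(self._separated(), n_perm=199, seed=0, unit="seed")
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_reproducible_given_seed(self):
        a = permutation_test(self._separated(), n_perm=199, seed=7)
        b = permutation_test(self._separated(), n_perm=199, seed=7)
        assert a.p_value == b.p_value

    def test_few_permutations_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            permutation_test(self._separated(), n_perm=50, seed=0)

    def test_single_group_errors(self):
        data = make_intervals([(0, 1)] * 8, dish=["d1"] * 4 + ["d2"] * 4)
        with pytest.raises(ValueError):
            permutation_test(data, n_perm=99, seed=0)

    def test_dish_spanning_groups_rejected(self):
        data = make_intervals(
            [(0, 1)] * 4,
            group=["A", "A", "B", "B"],
            dish=["d1", "d1", "d1", "d2"],
        )
        with pytest.raises(ValueError, match="spans multiple groups"):
            permutation_test(data, n_perm=99, seed=0)
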