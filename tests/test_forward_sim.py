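import numpy as np
import pytest

import breedopt as bo
from breedopt.environment import ParameterError


@pytest.fixture(scope="module")
def capital_a3_policy(default_params, default_sched):
    dist = bo.discretize_food_gain(3.0, default_params)
    vt, _ = bo.backward_induction_capital(default_params, dist, default_sched)
    return vt, dist


class TestSingleFemale:
    def test_deterministic_capital_outcome_structure(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        o = bo.simulate_female(
            vt, 90, dist, default_params, default_sched, rng=1
        )
        assert o.bred
        assert 90 <= o.first_egg_day
        assert o.first_egg_day >= default_params.b_s
        # uninterrupted daily laying: incubation starts right after egg n
        assert o.incubation_day - o.first_egg_day == o.clutch
        assert o.hatch_day - o.incubation_day == default_params.I
        f_hatch = bo.recruitment_probability(o.hatch_day, default_sched)
        assert o.recruits == pytest.approx(o.clutch * f_hatch)

    def test_deterministic_policy_achieves_dp_value_exactly(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        for arrival in (80, 90, 100, 120):
            o = bo.simulate_female(
                vt, arrival, dist, default_params, default_sched, rng=0
            )
            assert o.recruits == pytest.approx(
                vt.value(0, arrival, 0), abs=1e-9
            )

    def test_no_foraging_after_first_egg_for_capital(
        self, capital_a3_policy, default_params, default_sched
    ):
        vt, dist = capital_a3_policy
        o = bo.simulate_female(
            vt, 90, dist, default_params, default_sched, rng=11
        )
        # after t*, reserves only ever fall by the egg cost until incubation
        lay_days = range(o.first_egg_day, o.incubation_day)
        diffs = np.diff(o.reserves[o.first_egg_day : o.incubation_day + 1])
        assert len(list(lay_days)) == o.clutch
        np.testing.assert_allclose(diffs, -default_params.egg_cost)

    def test_reserves_stay_within_physiological_bounds(
        self, capital_a3_policy, default_params, default_sched
    ):
        vt, dist = capital_a3_policy
        for seed in range(5):
            o = bo.simulate_female(
                vt, 85, dist, default_params, default_sched, rng=seed
            )
            traj = o.reserves[~np.isnan(o.reserves)]
            assert traj.min() >= 0.0
            assert traj.max() <= default_params.S_max_capital + 1e-9

    def test_income_interleaves_foraging_between_eggs(
        self, income_det_policy, default_params, default_sched
    ):
        # deterministic gain: each egg needs ceil(cE / w_a) = 11 foraging
        # days, so consecutive eggs are 12 days apart
        vt, _, dist = income_det_policy
        o = bo.simulate_female(
            vt, 90, dist, default_params, default_sched, rng=2
        )
        traj = o.reserves
        lay_days = [
            t
            for t in range(o.first_egg_day, o.incubation_day)
            if traj[t + 1] - traj[t] < -100
        ]
        assert len(lay_days) == o.clutch
        gaps = np.diff(lay_days)
        assert (gaps == 12).all()
        assert o.incubation_day - o.first_egg_day >= o.clutch

    def test_no_laying_before_spring_onset(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        o = bo.simulate_female(
            vt, 50, dist, default_params, default_sched, rng=3
        )
        assert o.first_egg_day >= default_params.b_s

    def test_policy_params_mismatch_rejected(
        self, capital_det_policy, default_sched
    ):
        vt, _, dist = capital_det_policy
        other = bo.ModelParams(b_s=110)
        with pytest.raises(ParameterError, match="different parameters"):
            bo.simulate_female(vt, 90, dist, other, default_sched, rng=0)

    def test_arrival_outside_season_rejected(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        with pytest.raises(ParameterError):
            bo.simulate_female(
                vt, 0, dist, default_params, default_sched, rng=0
            )


class TestPopulation:
    def test_cohort_size_and_seed_reproducibility(
        self, capital_a3_policy, default_params, default_sched
    ):
        vt, dist = capital_a3_policy
        params = default_params.replace(N_pop=300)
        cohort = bo.sample_arrival_days(params, 5)
        out1 = bo.simulate_population(
            vt, cohort, dist, params, default_sched, seed=6
        )
        out2 = bo.simulate_population(
            vt, cohort, dist, params, default_sched, seed=6
        )
        out3 = bo.simulate_population(
            vt, cohort, dist, params, default_sched, seed=7
        )
        assert len(out1) == 300
        assert [o.recruits for o in out1] == [o.recruits for o in out2]
        assert [o.recruits for o in out1] != [o.recruits for o in out3]

    def test_deterministic_income_recruit_variance_collapses(
        self, income_det_policy, default_params, default_sched
    ):
        # constant food: on-time income breeders all follow one strategy
        vt, _, dist = income_det_policy
        params = default_params.replace(N_pop=400)
        cohort = bo.sample_arrival_days(params, 8)
        out = bo.simulate_population(
            vt, cohort, dist, params, default_sched, seed=8
        )
        on_time = [
            o.recruits
            for o in out
            if o.arrival_day <= params.b_s - int(np.ceil(params.egg_cost / params.w_a))
        ]
        assert len(on_time) > 100
        assert np.var(on_time) == pytest.approx(0.0, abs=1e-12)

    def test_late_arrivals_fail_gracefully(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        cohort = bo.ArrivalCohort(np.array([235, 238, 240]))
        out = bo.simulate_population(
            vt, cohort, dist, default_params, default_sched, seed=9
        )
        assert all(o.recruits == 0.0 and not o.bred for o in out)


class TestSummaries:
    def _outcome(self, arrival, t_star, t_inc, clutch, hatch, recruits):
        return bo.FemaleOutcome(
            arrival_day=arrival,
            first_egg_day=t_star,
            incubation_day=t_inc,
            clutch=clutch,
            hatch_day=hatch,
            recruits=recruits,
        )

    def test_identical_broods_have_zero_variance(self):
        outcomes = [self._outcome(90, 110, 114, 4, 140, 4.0) for _ in range(10)]
        s = bo.summarize_population(outcomes, b_s=100)
        assert s.mean_recruits == 4.0
        assert s.var_recruits == 0.0
        assert s.mean_clutch == 4.0
        assert s.mean_onset_rel_bs == 10.0
        assert s.frac_failed == 0.0

    def test_failures_count_toward_population_mean(self):
        half_fail = [self._outcome(90, None, None, 0, None, 0.0)] * 5 + [
            self._outcome(90, 100, 102, 2, 128, 2.0)
        ] * 5
        s = bo.summarize_population(half_fail, b_s=100)
        assert s.mean_recruits == 1.0
        assert s.frac_failed == 0.5
        assert s.mean_clutch == 2.0  # averaged over breeders only

    def test_mean_recruits_bounded_by_max_brood(
        self, capital_a3_policy, default_params, default_sched
    ):
        vt, dist = capital_a3_policy
        params = default_params.replace(N_pop=200)
        cohort = bo.sample_arrival_days(params, 3)
        out = bo.simulate_population(
            vt, cohort, dist, params, default_sched, seed=4
        )
        s = bo.summarize_population(out, b_s=params.b_s, sched=default_sched)
        assert 0.0 <= s.mean_recruits <= params.n_max * params.f_max

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            bo.summarize_population([], b_s=100)

    def test_outcomes_frame_columns(
        self, capital_det_policy, default_params, default_sched
    ):
        vt, _, dist = capital_det_policy
        cohort = bo.ArrivalCohort(np.array([90, 95]))
        out = bo.simulate_population(
            vt, cohort, dist, default_params, default_sched, seed=2
        )
        df = bo.outcomes_to_frame(out)
        assert list(df.columns) == [
            "arrival_day",
            "first_egg_day",
            "incubation_day",
            "clutch",
            "hatch_day",
            "recruits",
        ]
        assert len(df) == 2
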