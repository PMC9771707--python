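import numpy as np
import pytest

import breedopt as bo


@pytest.fixture(scope="session")
def default_params() -> bo.ModelParams:
    return bo.ModelParams()


@pytest.fixture(scope="session")
def default_sched(default_params) -> bo.RecruitmentSchedule:
    return bo.RecruitmentSchedule.from_params(default_params)


@pytest.fixture(scope="session")
def tiny_capital():
    """Hand-enumerable instance: T=6, unit egg cost, 2-egg clutch cap.

    The optimal plan from (S=0, t=1, n=0) is forage day 1, lay day 2,
    incubate day 3, hatch day 5, giving 1 egg x f(5) = 0.2 recruits.
    """
    params = bo.ModelParams(
        E=1.0, c=1.0, n_max=2, I=2, i_hatch=2, w_a=1.0, k=2,
        b_s=1, b_ref=1, T=6, dS=1.0, S_max_capital=2.0,
        D_a=1, SD_a=0, N_pop=1,
    )
    dist = bo.deterministic_food_gain(params)
    sched = bo.RecruitmentSchedule.from_params(params)
    return params, dist, sched


@pytest.fixture(scope="session")
def small_stochastic():
    """Two-outcome instance whose reachable reserves all land on the grid."""
    params = bo.ModelParams(
        E=2.0, c=1.0, n_max=2, I=2, i_hatch=2, w_a=2.0, k=2,
        b_s=2, b_ref=1, T=8, dS=1.0, S_max_capital=4.0,
        D_a=1, SD_a=0, N_pop=1,
    )
    dist = bo.FoodGainDistribution(
        support=np.array([1.0, 3.0]), probs=np.array([0.5, 0.5])
    )
    sched = bo.RecruitmentSchedule.from_params(params)
    return params, dist, sched


@pytest.fixture(scope="session")
def capital_det_policy(default_params, default_sched):
    dist = bo.deterministic_food_gain(default_params)
    vt, pt = bo.backward_induction_capital(default_params, dist, default_sched)
    return vt, pt, dist


@pytest.fixture(scope="session")
def income_det_policy(default_params, default_sched):
    dist = bo.deterministic_food_gain(default_params)
    vt, pt = bo.backward_induction_income(default_params, dist, default_sched)
    return vt, pt, dist
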