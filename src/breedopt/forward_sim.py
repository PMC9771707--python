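"""Monte-Carlo simulation of females following the optimal policy.

Each simulated female starts lean on her arrival day and, every day,
takes the feasible action with the highest expected value. Action values
are recomputed from the value function at her *continuous* reserve level
by linear interpolation — the same interpolation used during backward
induction — rather than read off the nearest grid node, so the forward
behaviour is exactly the policy the optimization valued. Daily food gains
are drawn independently per female from the same distribution the policy
was optimized against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dp_core import _forage_allowed, ValueTable, interpolate_value
from .environment import (
    ArrivalCohort,
    FoodGainDistribution,
    ModelParams,
    ParameterError,
    sample_gain_indices,
)
from .recruitment import RecruitmentSchedule, recruitment_probability

__all__ = [
    "FemaleOutcome",
    "PopulationSummary",
    "simulate_female",
    "simulate_population",
    "summarize_population",
    "outcomes_to_frame",
]


@dataclass(frozen=True)
class FemaleOutcome:
    """One simulated female's breeding season."""

    arrival_day: int
    first_egg_day: int | None  # t*: nesting onset
    incubation_day: int | None  # t***: laying terminated, incubation starts
    clutch: int
    hatch_day: int | None
    recruits: float
    reserves: np.ndarray | None = None  # S(t) by day of year, NaN outside season

    @property
    def bred(self) -> bool:
        return self.hatch_day is not None


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level means over a simulated cohort.

    Nesting onset (relative to the spring onset ``b_s``) and clutch size
    average over females that laid at least one egg; recruitment
    probability averages over hatched clutches; recruits average over the
    whole cohort, failures contributing 0 (variance likewise, with the
    cohort size as denominator).
    """

    n_females: int
    mean_onset_rel_bs: float
    mean_clutch: float
    mean_recruit_prob: float
    mean_recruits: float
    var_recruits: float
    se_mean_recruits: float
    frac_failed: float


def _check_policy(value_table: ValueTable, params: ModelParams) -> None:
    S_max = (
        params.S_max_capital
        if value_table.strategy == "capital"
        else params.S_max_income
    )
    if (
        value_table.T != params.T
        or value_table.b_s != params.b_s
        or abs(value_table.grid.S_max - S_max) > 1e-9
    ):
        raise ParameterError(
            "value table was built with different parameters than supplied"
        )


def _run_cohort(
    value_table: ValueTable,
    arrivals: np.ndarray,
    gains: np.ndarray,
    dist: FoodGainDistribution,
    params: ModelParams,
    sched: RecruitmentSchedule,
    record_reserves: bool = False,
):
    """Vectorized day-by-day simulation of a cohort.

    ``gains[j, t]`` is female *j*'s net food gain if she forages on day
    ``t``; draws on non-foraging days stay unused. Returns parallel arrays
    (first-egg day, incubation day, clutch, hatch day, recruits, and
    optionally the reserve trajectories), with -1 marking "never".
    """
    V, grid, strategy = value_table.V, value_table.grid, value_table.strategy
    T, n_max, cE = params.T, params.n_max, params.egg_cost
    b_s, I, i_hatch = params.b_s, params.I, params.i_hatch
    N = arrivals.size

    S = np.zeros(N)
    eggs = np.zeros(N, dtype=np.int64)
    finished = np.zeros(N, dtype=bool)
    t_star = np.full(N, -1, dtype=np.int64)
    t_inc = np.full(N, -1, dtype=np.int64)
    hatch = np.full(N, -1, dtype=np.int64)
    recruits = np.zeros(N)
    traj = np.full((N, T + 1), np.nan) if record_reserves else None
    support = dist.support

    for t in range(max(int(arrivals.min()), 1), T):
        alive = ~finished & (arrivals <= t)
        if not alive.any():
            continue
        if traj is not None:
            traj[alive, t] = S[alive]
        idx_alive = np.nonzero(alive)[0]
        eggs_today = eggs[idx_alive].copy()  # snapshot: one action per day
        for nv in np.unique(eggs_today):
            nv = int(nv)
            idx = idx_alive[eggs_today == nv]
            Sg = S[idx]
            # candidate rows in tie-break priority: incubate, lay, forage
            cand = np.full((3, idx.size), -np.inf)
            if nv >= 1 and b_s <= t <= T - I:
                cand[0] = nv * recruitment_probability(t + i_hatch, sched)
            if nv < n_max and t >= b_s:
                v_lay = interpolate_value(V[nv + 1, t + 1], grid, Sg - cE)
                cand[1] = np.where(Sg >= cE - 1e-9, v_lay, -np.inf)
            if _forage_allowed(strategy, nv, n_max):
                land = np.clip(Sg[None, :] + support[:, None], 0.0, grid.S_max)
                cand[2] = dist.probs @ np.interp(land, grid.S_nodes, V[nv, t + 1])
            choice = cand.argmax(axis=0)
            feasible = np.isfinite(cand.max(axis=0))

            inc_sel = idx[feasible & (choice == 0)]
            if inc_sel.size:
                finished[inc_sel] = True
                t_inc[inc_sel] = t
                hatch[inc_sel] = t + i_hatch
                recruits[inc_sel] = nv * recruitment_probability(
                    t + i_hatch, sched
                )
            lay_sel = idx[feasible & (choice == 1)]
            if lay_sel.size:
                S[lay_sel] -= cE
                eggs[lay_sel] += 1
                if nv == 0:
                    t_star[lay_sel] = t
            forage_sel = idx[feasible & (choice == 2)]
            if forage_sel.size:
                S[forage_sel] = np.clip(
                    S[forage_sel] + gains[forage_sel, t], 0.0, grid.S_max
                )
    if traj is not None:
        done = hatch >= 0
        # freeze the trajectory at the incubation level for bookkeeping
        for j in np.nonzero(done)[0]:
            traj[j, t_inc[j] :] = S[j]
    return t_star, t_inc, eggs, hatch, recruits, traj


def _draw_gains(
    dist: FoodGainDistribution, rngs: list[np.random.Generator], T: int
) -> np.ndarray:
    """One gain per female per day of year, drawn from per-female streams."""
    gains = np.empty((len(rngs), T + 1))
    for j, rng in enumerate(rngs):
        gains[j] = dist.support[sample_gain_indices(dist, rng, T + 1)]
    return gains


def _build_outcomes(arrivals, t_star, t_inc, eggs, hatch, recruits, traj):
    out = []
    for j in range(arrivals.size):
        out.append(
            FemaleOutcome(
                arrival_day=int(arrivals[j]),
                first_egg_day=int(t_star[j]) if t_star[j] >= 0 else None,
                incubation_day=int(t_inc[j]) if t_inc[j] >= 0 else None,
                clutch=int(eggs[j]),
                hatch_day=int(hatch[j]) if hatch[j] >= 0 else None,
                recruits=float(recruits[j]),
                reserves=traj[j] if traj is not None else None,
            )
        )
    return out


def simulate_female(
    value_table: ValueTable,
    arrival: int,
    dist: FoodGainDistribution,
    params: ModelParams,
    sched: RecruitmentSchedule,
    rng: np.random.Generator | int | None = None,
    record_reserves: bool = True,
) -> FemaleOutcome:
    """Simulate a single female arriving on ``arrival`` with zero reserves."""
    _check_policy(value_table, params)
    if not 1 <= arrival <= params.T:
        raise ParameterError(f"arrival day {arrival} outside [1, {params.T}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    arrivals = np.array([arrival], dtype=np.int64)
    gains = _draw_gains(dist, [rng], params.T)
    res = _run_cohort(
        value_table, arrivals, gains, dist, params, sched, record_reserves
    )
    return _build_outcomes(arrivals, *res)[0]


def simulate_population(
    value_table: ValueTable,
    cohort: ArrivalCohort,
    dist: FoodGainDistribution,
    params: ModelParams,
    sched: RecruitmentSchedule,
    seed: int | None = None,
    record_reserves: bool = False,
) -> list[FemaleOutcome]:
    """Simulate every female of the cohort under independent daily gains.

    Each female forages on her own child RNG stream (spawned from
    ``seed``), so her draw sequence does not depend on the cohort size or
    on the other females.
    """
    _check_policy(value_table, params)
    arrivals = cohort.arrival_days
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(arrivals.size)]
    gains = _draw_gains(dist, rngs, params.T)
    res = _run_cohort(
        value_table, arrivals, gains, dist, params, sched, record_reserves
    )
    return _build_outcomes(arrivals, *res)


def outcomes_to_frame(outcomes: list[FemaleOutcome]) -> pd.DataFrame:
    """One row per female: arrival, t*, t***, clutch, hatch day, recruits."""
    return pd.DataFrame(
        {
            "arrival_day": [o.arrival_day for o in outcomes],
            "first_egg_day": [o.first_egg_day for o in outcomes],
            "incubation_day": [o.incubation_day for o in outcomes],
            "clutch": [o.clutch for o in outcomes],
            "hatch_day": [o.hatch_day for o in outcomes],
            "recruits": [o.recruits for o in outcomes],
        }
    )


def summarize_population(
    outcomes: list[FemaleOutcome],
    b_s: int,
    sched: RecruitmentSchedule | None = None,
) -> PopulationSummary:
    """Population summary of a simulated cohort.

    ``sched`` is only needed to report the mean recruitment probability at
    hatch; if omitted, that field is derived as recruits/clutch per hatched
    female, which is identical by construction.
    """
    if not outcomes:
        raise ParameterError("cannot summarize an empty cohort")
    N = len(outcomes)
    recruits = np.array([o.recruits for o in outcomes])
    onset = np.array(
        [o.first_egg_day for o in outcomes if o.first_egg_day is not None],
        dtype=float,
    )
    clutch_breeders = np.array(
        [o.clutch for o in outcomes if o.first_egg_day is not None], dtype=float
    )
    hatched = [o for o in outcomes if o.hatch_day is not None]
    if sched is not None:
        f_at_hatch = np.array(
            [recruitment_probability(o.hatch_day, sched) for o in hatched]
        )
    else:
        f_at_hatch = np.array(
            [o.recruits / o.clutch for o in hatched if o.clutch > 0]
        )
    return PopulationSummary(
        n_females=N,
        mean_onset_rel_bs=float(onset.mean() - b_s) if onset.size else np.nan,
        mean_clutch=float(clutch_breeders.mean()) if clutch_breeders.size else np.nan,
        mean_recruit_prob=float(f_at_hatch.mean()) if f_at_hatch.size else np.nan,
        mean_recruits=float(recruits.mean()),
        var_recruits=float(recruits.var()),
        se_mean_recruits=float(recruits.std(ddof=1) / np.sqrt(N)) if N > 1 else np.nan,
        frac_failed=float(np.mean([o.hatch_day is None for o in outcomes])),
    )
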