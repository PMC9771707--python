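"""Seasonal recruitment decline and the incubation payoff.

An offspring's chance of recruiting falls linearly with its hatch date:
it is maximal (``f_max``) at the first possible breeding day of the
earliest season considered (``b_ref``) and reaches 0 at the season end
``T``, when it is too late for a duckling to develop before autumn
migration. A female that starts incubating a clutch of ``n`` eggs on day
``t`` hatches it ``i_hatch`` days later and collects the terminal fitness
``n * f(t + i_hatch)`` expected recruits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import ModelParams, ParameterError

__all__ = ["RecruitmentSchedule", "recruitment_probability", "incubation_payoff"]


@dataclass(frozen=True)
class RecruitmentSchedule:
    """Linear hatch-date -> recruitment-probability map.

    ``f(t) = f_max * (T - t) / (T - b_ref)``, clamped to ``[0, f_max]``.
    """

    b_ref: int
    T: int
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if self.b_ref >= self.T:
            raise ParameterError(f"need b_ref < T (got {self.b_ref}, {self.T})")
        if not (0.0 < self.f_max <= 1.0):
            raise ParameterError(f"need 0 < f_max <= 1 (got {self.f_max})")

    @classmethod
    def from_params(cls, params: ModelParams) -> "RecruitmentSchedule":
        return cls(b_ref=params.b_ref, T=params.T, f_max=params.f_max)

    def __call__(self, t):
        return recruitment_probability(t, self)


def recruitment_probability(t, sched: RecruitmentSchedule):
    """Probability that an offspring hatched on day ``t`` recruits.

    Accepts scalars or arrays; clamps at ``f_max`` before ``b_ref`` and at 0
    from ``T`` onward.
    """
    t = np.asarray(t, dtype=float)
    f = sched.f_max * (sched.T - t) / (sched.T - sched.b_ref)
    out = np.clip(f, 0.0, sched.f_max)
    return float(out) if out.ndim == 0 else out


def incubation_payoff(
    t: int, n: int, params: ModelParams, sched: RecruitmentSchedule
) -> float:
    """Expected recruits from starting incubation on day ``t`` with ``n`` eggs.

    Incubation is terminal: the clutch hatches ``i_hatch`` days later and no
    further decisions are taken. Outside the feasible window
    ``b_s <= t <= T - I`` the payoff is ``-inf`` (the action is excluded
    from any maximization).
    """
    if not 0 <= n <= params.n_max:
        raise ParameterError(f"clutch size {n} outside [0, {params.n_max}]")
    if not params.b_s <= t <= params.T - params.I:
        return -np.inf
    return n * recruitment_probability(t + params.i_hatch, sched)
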