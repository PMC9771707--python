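"""Backward induction of the optimal forage/lay/incubate policy.

The state is (reserves ``S``, day ``t``, eggs laid ``n``). Each day a
female takes exactly one action:

* **forage** — reserves change by a random daily gain, clamped to
  ``[0, S_max]``. Capital breeders forage only before the first egg
  (``n = 0``); income breeders may forage at any ``n < n_max``.
* **lay** — costs ``c*E`` grams of reserves and adds one egg; available
  from the spring onset ``b_s`` while ``S >= c*E`` and ``n < n_max``.
* **incubate** — terminal: the clutch hatches ``i_hatch`` days later and
  pays ``n * f(hatch day)`` expected recruits; available for
  ``b_s <= t <= T - I`` and at least one egg.

Values are computed on a uniform reserve grid; reserves off the grid are
valued by linear interpolation, the standard device for continuous states
in dynamic state variable models. The induction runs from the terminal
day ``T`` (value 0 for every non-incubated state) down to day 1.

The two strategies differ only in the reserve cap (``S_max_capital``
versus the single-egg cost ``c*E``) and in when foraging is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .environment import FoodGainDistribution, ModelParams, ParameterError
from .recruitment import RecruitmentSchedule, incubation_payoff

__all__ = [
    "StateGrid",
    "ValueTable",
    "PolicyTable",
    "interpolate_value",
    "backward_induction",
    "backward_induction_capital",
    "backward_induction_income",
    "brute_force_value_oracle",
]

Strategy = Literal["capital", "income"]

# action codes in tie-break priority order: under an exact tie earlier
# reproduction is weakly better given the non-increasing recruitment curve
ACTION_NONE = 0
ACTION_INCUBATE = 1
ACTION_LAY = 2
ACTION_FORAGE = 3
ACTION_NAMES = {0: "none", 1: "incubate", 2: "lay", 3: "forage"}


@dataclass(frozen=True)
class StateGrid:
    """Uniform reserve grid 0, dS, ..., S_max for one strategy."""

    S_nodes: np.ndarray
    S_max: float
    dS: float

    @classmethod
    def for_strategy(cls, params: ModelParams, strategy: Strategy) -> "StateGrid":
        S_max = params.S_max_capital if strategy == "capital" else params.S_max_income
        n_steps = S_max / params.dS
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ParameterError(
                f"S_max={S_max} is not a multiple of dS={params.dS}; "
                "the grid must contain both 0 and S_max exactly"
            )
        nodes = np.linspace(0.0, S_max, round(n_steps) + 1)
        return cls(S_nodes=nodes, S_max=float(S_max), dS=float(params.dS))


@dataclass(frozen=True)
class ValueTable:
    """Expected future recruits ``V[n, t, S-node]`` plus its state grid.

    The day axis has length ``T + 1`` and is indexed directly by day of
    year (index 0 is unused); ``V[:, T, :] = 0`` is the terminal condition.
    """

    V: np.ndarray
    grid: StateGrid
    strategy: Strategy
    b_s: int
    T: int

    def value(self, S: float, t: int, n: int) -> float:
        """Interpolated value at continuous reserves ``S``."""
        return float(interpolate_value(self.V[n, t], self.grid, S))

    def to_frame(self) -> pd.DataFrame:
        n_eggs, n_days, n_nodes = self.V.shape
        n_idx, t_idx, s_idx = np.meshgrid(
            np.arange(n_eggs), np.arange(1, n_days), np.arange(n_nodes),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "S": self.grid.S_nodes[s_idx.ravel()],
                "t": t_idx.ravel(),
                "n": n_idx.ravel(),
                "V": self.V[:, 1:, :].ravel(),
            }
        )


@dataclass(frozen=True)
class PolicyTable:
    """Optimal action per lattice point, same layout as :class:`ValueTable`."""

    action: np.ndarray
    grid: StateGrid
    strategy: Strategy

    def to_frame(self) -> pd.DataFrame:
        n_eggs, n_days, n_nodes = self.action.shape
        n_idx, t_idx, s_idx = np.meshgrid(
            np.arange(n_eggs), np.arange(1, n_days), np.arange(n_nodes),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "S": self.grid.S_nodes[s_idx.ravel()],
                "t": t_idx.ravel(),
                "n": n_idx.ravel(),
                "action": [
                    ACTION_NAMES[a] for a in self.action[:, 1:, :].ravel()
                ],
            }
        )

    def export_csv(self, path: str | Path, value_table: ValueTable) -> None:
        df = value_table.to_frame()
        df["action"] = self.to_frame()["action"]
        df.to_csv(path, index=False)


def interpolate_value(V_slice: np.ndarray, grid: StateGrid, S) -> np.ndarray:
    """Piecewise-linear value at reserves ``S`` (scalar or array).

    Reserves above ``S_max`` are first clamped to the cap; below 0 cannot
    occur by construction but are clamped defensively.
    """
    S = np.clip(S, 0.0, grid.S_max)
    return np.interp(S, grid.S_nodes, V_slice)


def _forage_allowed(strategy: Strategy, n: int, n_max: int) -> bool:
    return n == 0 if strategy == "capital" else n < n_max


def backward_induction(
    params: ModelParams,
    dist: FoodGainDistribution,
    sched: RecruitmentSchedule,
    strategy: Strategy,
) -> tuple[ValueTable, PolicyTable]:
    """Solve the Bellman recursion for one breeding strategy.

    Returns the value function on the (reserves x day x eggs) lattice and
    the optimal action at each lattice point. Infeasible actions are
    excluded from the maximum (not clamped to zero), so states where no
    action is feasible carry value 0 and the ``none`` action: genuinely
    failed breeders.
    """
    if strategy not in ("capital", "income"):
        raise ParameterError(f"unknown strategy {strategy!r}")
    grid = StateGrid.for_strategy(params, strategy)
    if params.egg_cost > grid.S_max + 1e-9:
        raise ParameterError("egg cost c*E exceeds the reserve cap S_max")

    nS = grid.S_nodes.size
    T, n_max = params.T, params.n_max
    V = np.zeros((n_max + 1, T + 1, nS))
    action = np.zeros((n_max + 1, T + 1, nS), dtype=np.int8)

    lay_feasible_S = grid.S_nodes >= params.egg_cost - 1e-9
    lay_from = grid.S_nodes - params.egg_cost
    forage_to = np.clip(
        grid.S_nodes[None, :] + dist.support[:, None], 0.0, grid.S_max
    )  # (k, nS) landing reserves

    neg = -np.inf
    for t in range(T - 1, 0, -1):
        for n in range(n_max + 1):
            cand = np.full((3, nS), neg)
            # incubate (priority row 0): terminal payoff, scalar across S
            if n >= 1:
                cand[0] = incubation_payoff(t, n, params, sched)
            # lay (row 1)
            if n < n_max and t >= params.b_s:
                v_lay = interpolate_value(V[n + 1, t + 1], grid, lay_from)
                cand[1] = np.where(lay_feasible_S, v_lay, neg)
            # forage (row 2)
            if _forage_allowed(strategy, n, n_max):
                v_next = V[n, t + 1]
                cand[2] = dist.probs @ np.interp(forage_to, grid.S_nodes, v_next)
            best = cand.max(axis=0)
            best_a = cand.argmax(axis=0) + 1  # priority order -> action code
            dead = ~np.isfinite(best)
            V[n, t] = np.where(dead, 0.0, best)
            action[n, t] = np.where(dead, ACTION_NONE, best_a)

    vt = ValueTable(V=V, grid=grid, strategy=strategy, b_s=params.b_s, T=T)
    pt = PolicyTable(action=action, grid=grid, strategy=strategy)
    return vt, pt


def backward_induction_capital(
    params: ModelParams, dist: FoodGainDistribution, sched: RecruitmentSchedule
) -> tuple[ValueTable, PolicyTable]:
    """Capital breeder: reserve cap ``S_max_capital``; foraging stops at the
    first egg."""
    return backward_induction(params, dist, sched, "capital")


def backward_induction_income(
    params: ModelParams, dist: FoodGainDistribution, sched: RecruitmentSchedule
) -> tuple[ValueTable, PolicyTable]:
    """Income breeder: reserve cap ``c*E`` (one egg's cost); foraging is
    allowed between laying days."""
    return backward_induction(params, dist, sched, "income")


def brute_force_value_oracle(
    params: ModelParams,
    dist: FoodGainDistribution,
    sched: RecruitmentSchedule,
    S0: float,
    t0: int,
    n0: int,
    strategy: Strategy = "capital",
    _max_T: int = 14,
    _max_k: int = 3,
) -> float:
    """Exact optimal value by exhaustive enumeration (test oracle).

    Recursively enumerates every feasible action sequence from
    ``(S0, t0, n0)``, taking exact expectations over the food-outcome tree
    — no reserve grid, no interpolation. Exponential in the horizon, so it
    refuses instances beyond ``T <= 14`` or ``k <= 3``.
    """
    if params.T > _max_T or dist.support.size > _max_k:
        raise ParameterError(
            f"instance too large to enumerate (T={params.T}, k={dist.support.size})"
        )
    S_max = params.S_max_capital if strategy == "capital" else params.S_max_income
    cE, n_max, T = params.egg_cost, params.n_max, params.T

    def rec(S: float, t: int, n: int) -> float:
        if t >= T:
            return 0.0
        best = None
        if n >= 1:
            inc = incubation_payoff(t, n, params, sched)
            if np.isfinite(inc):
                best = inc
        if n < n_max and t >= params.b_s and S >= cE - 1e-9:
            v = rec(S - cE, t + 1, n + 1)
            best = v if best is None else max(best, v)
        if _forage_allowed(strategy, n, n_max):
            v = sum(
                p * rec(min(max(S + w, 0.0), S_max), t + 1, n)
                for p, w in zip(dist.probs, dist.support)
            )
            best = v if best is None else max(best, v)
        return 0.0 if best is None else best

    return rec(min(float(S0), S_max), int(t0), int(n0))
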