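"""Model parameters and stochastic inputs.

This module holds every tunable constant of the breeding model and builds
the two stochastic inputs the rest of the pipeline consumes:

* a discretized daily net food-gain distribution (a symmetric beta law
  rescaled to ``[x1*w_a, x2*w_a]`` and collapsed to ``k`` outcome types), and
* a cohort of integer arrival days drawn from a normal migration schedule.

Reserves, egg costs and gains are all in grams; time is in integer days of
the year.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "ModelParams",
    "FoodGainDistribution",
    "ArrivalCohort",
    "discretize_food_gain",
    "deterministic_food_gain",
    "sample_daily_gain",
    "sample_arrival_days",
]


class ParameterError(ValueError):
    """An inconsistent or out-of-range model parameter."""


@dataclass(frozen=True)
class ModelParams:
    """All constants of the breeding model.

    Parameters
    ----------
    E : float
        Egg mass (g). Each egg allocates ``E`` grams of reserves to egg
        material.
    c : float
        Reserve-cost multiplier per egg. The per-egg reserve decrement is
        ``c * E``; the factor above 1 prepays the incubation surcharge
        (50% of egg production costs at the default ``c = 1.5``).
    n_max : int
        Maximal clutch size (eggs).
    I : int
        Incubation duration (days).
    i_hatch : int or None
        Days from the last egg laid to hatching. ``None`` means "equal to
        the incubation duration ``I``", the only internally consistent
        default since incubation starts when laying ends.
    w_a : float
        Mean net daily food gain (g/day).
    x1, x2 : float
        Lower/upper gain multipliers: daily gain lies in
        ``[x1 * w_a, x2 * w_a]``.
    k : int
        Number of discrete foraging-outcome types.
    alpha : float
        Shape parameter of the symmetric beta law (alpha = beta) that
        weights the outcome types. Larger alpha means lower variance.
    b_s : int
        First possible breeding (nesting) day — the spring onset.
    b_ref : int
        Earliest ``b_s`` across a scenario sweep; anchors the recruitment
        decline.
    T : int
        Season end day (autumn migration); recruitment reaches 0 here.
    M_L : float
        Lean body mass (g); only used for the body-mass cap diagnostic.
    S_max_capital : float
        Reserve cap for capital breeders (g). The default equals
        ``n_max * c * E``, the smallest cap that makes a full clutch
        attainable, and also 30% of the lean mass.
    S_min : float
        Reserves at arrival (g); females arrive lean.
    f_max : float
        Recruitment probability at ``b_ref``.
    D_a, SD_a : float
        Mean and SD of the arrival day distribution.
    N_pop : int
        Cohort size for forward simulation.
    dS : float
        Reserve-grid step (g) for the dynamic program.
    seed : int
        Top-level RNG seed.
    """

    E: float = 110.0
    c: float = 1.5
    n_max: int = 7
    I: int = 26
    i_hatch: int | None = None
    w_a: float = 15.0
    x1: float = -1.0
    x2: float = 3.0
    k: int = 20
    alpha: float = 3.0
    b_s: int = 100
    b_ref: int = 100
    T: int = 240
    M_L: float = 3850.0
    S_max_capital: float = 1155.0
    S_min: float = 0.0
    f_max: float = 1.0
    D_a: float = 90.0
    SD_a: float = 10.0
    N_pop: int = 10_000
    dS: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i_hatch is None:
            object.__setattr__(self, "i_hatch", self.I)
        if self.x1 >= self.x2:
            raise ParameterError(f"x1 must be < x2 (got {self.x1}, {self.x2})")
        if self.k < 2:
            raise ParameterError(f"k must be >= 2 (got {self.k})")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be > 0 (got {self.alpha})")
        if self.dS <= 0:
            raise ParameterError(f"dS must be > 0 (got {self.dS})")
        if not (self.S_min == 0.0 < self.egg_cost <= self.S_max_capital):
            raise ParameterError(
                "need 0 = S_min < c*E <= S_max_capital "
                f"(got S_min={self.S_min}, cE={self.egg_cost}, "
                f"S_max_capital={self.S_max_capital})"
            )
        if not (self.b_ref <= self.b_s < self.T - self.I):
            raise ParameterError(
                f"need b_ref <= b_s < T - I (got {self.b_ref}, {self.b_s}, "
                f"{self.T - self.I})"
            )
        if (self.M_L + self.S_max_capital) / self.M_L > 1.30 + 1e-9:
            raise ParameterError(
                "maximal body mass exceeds 130% of lean mass: "
                f"(M_L + S_max_capital)/M_L = "
                f"{(self.M_L + self.S_max_capital) / self.M_L:.3f}"
            )
        if self.S_max_capital < self.n_max * self.egg_cost - 1e-9:
            warnings.warn(
                "S_max_capital < n_max*c*E: a full clutch is unattainable "
                "for capital breeders",
                stacklevel=2,
            )

    @property
    def egg_cost(self) -> float:
        """Reserve decrement per egg laid, ``c * E`` (g)."""
        return self.c * self.E

    @property
    def S_max_income(self) -> float:
        """Reserve cap for income breeders: the cost of one egg (g)."""
        return self.egg_cost

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a YAML or JSON config file.

        Every key must name a :class:`ModelParams` field; unknown keys are
        an error so typos cannot silently fall back to defaults.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class FoodGainDistribution:
    """A discrete distribution of daily net food gain.

    ``support[i]`` is the gain of outcome type *i* (g/day, possibly
    negative) and ``probs[i]`` its probability.
    """

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, float))
        object.__setattr__(self, "probs", np.asarray(self.probs, float))
        if self.support.shape != self.probs.shape or self.support.ndim != 1:
            raise ParameterError("support and probs must be 1-d and equal length")
        if np.any(self.probs < 0):
            raise ParameterError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ParameterError("probabilities must sum to 1")

    @property
    def mean(self) -> float:
        return float(self.probs @ self.support)

    @property
    def variance(self) -> float:
        return float(self.probs @ (self.support - self.mean) ** 2)

    @property
    def is_deterministic(self) -> bool:
        return self.support.size == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": np.arange(1, self.support.size + 1),
                "w_i": self.support,
                "p_i": self.probs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ArrivalCohort:
    """Integer arrival days of a simulated cohort."""

    arrival_days: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "arrival_days", np.asarray(self.arrival_days, dtype=np.int64)
        )

    def __len__(self) -> int:
        return int(self.arrival_days.size)


def discretize_food_gain(
    alpha: float, params: ModelParams | None = None
) -> FoodGainDistribution:
    """Collapse a symmetric beta(alpha, alpha) gain law to ``k`` outcomes.

    The unit interval is split into ``k`` equal-width bins; each bin's beta
    probability mass becomes ``p_i`` and its midpoint, rescaled to
    ``[x1*w_a, x2*w_a]``, becomes the gain ``w_i``. A final uniform shift of
    the support pins the discrete mean to ``w_a`` exactly (for a symmetric
    beta the shift is at numerical-noise level), so stochastic and
    deterministic scenarios share the same average gain.
    """
    params = params or ModelParams()
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0 (got {alpha})")
    k = params.k
    if k < 2:
        raise ParameterError(f"k must be >= 2 (got {k})")

    edges = np.linspace(0.0, 1.0, k + 1)
    probs = np.diff(stats.beta.cdf(edges, alpha, alpha))
    probs = probs / probs.sum()
    mids = (edges[:-1] + edges[1:]) / 2.0
    lo, hi = params.x1 * params.w_a, params.x2 * params.w_a
    support = lo + (hi - lo) * mids
    support = support + (params.w_a - probs @ support)  # exact mean pin
    return FoodGainDistribution(support=support, probs=probs)


def deterministic_food_gain(params: ModelParams | None = None) -> FoodGainDistribution:
    """The variance-free baseline: every day yields exactly ``w_a`` grams."""
    params = params or ModelParams()
    return FoodGainDistribution(support=np.array([params.w_a]), probs=np.array([1.0]))


def sample_daily_gain(
    dist: FoodGainDistribution, rng: np.random.Generator
) -> float:
    """Draw one day's net food gain from ``dist``."""
    if dist.is_deterministic:
        return float(dist.support[0])
    return float(dist.support[sample_gain_indices(dist, rng, 1)[0]])


def sample_gain_indices(
    dist: FoodGainDistribution, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` outcome-type indices by inverse CDF on uniforms.

    Using uniforms (rather than ``rng.choice``) makes draws comonotone
    across distributions that share the RNG stream, which the scenario
    sweep exploits as common random numbers.
    """
    u = rng.random(n)
    cdf = np.cumsum(dist.probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, u, side="right").clip(max=dist.support.size - 1)


def sample_arrival_days(
    params: ModelParams, rng: np.random.Generator | int | None = None
) -> ArrivalCohort:
    """Draw the cohort's arrival days: Normal(D_a, SD_a), rounded to the
    nearest day and clamped to ``[1, T]``."""
    if params.N_pop < 1:
        raise ParameterError("N_pop must be >= 1")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = params.seed if rng is None else rng
        rng = np.random.default_rng(seed)
    days = rng.normal(params.D_a, params.SD_a, size=params.N_pop)
    days = np.clip(np.rint(days).astype(np.int64), 1, params.T)
    return ArrivalCohort(arrival_days=days, seed=seed)
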