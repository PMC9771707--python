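# Methods

## Model

The model is a dynamic state variable formulation of single-brood
breeding in a seasonal environment. A female's state is (reserves *S* in
grams, day of year *t*, eggs laid *n*). Fitness is the expected number
of recruits, *n·f(t_c)*, where *t_c* is the hatch date and *f* the
recruitment probability of an offspring hatched that day.

Daily actions and transitions:

| action | availability | transition |
|---|---|---|
| forage | capital: only before the first egg; income: while *n* < *n*ₘₐₓ | *S* ← min(max(*S* + *w*, 0), *S*ₘₐₓ), *w* a random daily net gain |
| lay | *t* ≥ *b*ₛ, *S* ≥ *cE*, *n* < *n*ₘₐₓ | *S* ← *S* − *cE*, *n* ← *n* + 1 |
| incubate | *b*ₛ ≤ *t* ≤ *T* − *I*, *n* ≥ 1 | terminal; hatch at *t* + *I*, payoff *n·f*(*t* + *I*) |

Exactly one action per day. If no action is feasible the female idles
with value 0 (a failed breeder; the model has no mortality). The per-egg
reserve decrement *cE* prepays both the egg material (*E*) and the
incubation surcharge ((*c* − 1)·*E*), so no further reserves are deducted
when incubation starts; this single-decrement accounting is what makes
the income breeder's reserve ceiling of exactly one egg-cost coherent.
Incubation is its own action on the day after the last egg, and the
hatch date is the incubation day plus *I*.

The recruitment curve is
*f(t) = f*ₘₐₓ · (*T* − *t*) / (*T* − *b*_ref), clamped to [0, *f*ₘₐₓ]:
maximal at the anchor *b*_ref (the earliest spring onset considered in a
sweep, so that scenarios within one sweep share a common offspring-value
scale) and zero at the season end *T*.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| *E* | egg mass | 110 | g |
| *c* | per-egg reserve-cost multiplier | 1.5 | — |
| *n*ₘₐₓ | maximal clutch | 7 | eggs |
| *I* | incubation duration (= hatch delay) | 26 | d |
| *w*ₐ | mean net daily food gain | 15 | g/d |
| *x*₁, *x*₂ | gain bounds as multiples of *w*ₐ | −1, 3 | — |
| *k* | foraging outcome types | 20 | — |
| α | symmetric beta shape (α = β) | 3 | — |
| *b*ₛ | first possible breeding day | 100 | day |
| *b*_ref | sweep anchor of *f* | 100 | day |
| *T* | season end | 240 | day |
| *M*_L | lean body mass | 3850 | g |
| *S*ₘₐₓ (capital) | reserve cap, = *n*ₘₐₓ·*cE* = 0.3·*M*_L | 1155 | g |
| *S*ₘₐₓ (income) | reserve cap, = *cE* | 165 | g |
| *D*ₐ, SDₐ | arrival day mean and SD | 90, 10 | day |
| *N* | cohort size | 10,000 | — |
| d*S* | reserve-grid step | 5 | g |

*E*, *c*, *n*ₘₐₓ, *I*, *w*ₐ, *x*₁, *x*₂, *k*, the α range, *D*ₐ, SDₐ
and *N* are empirically grounded eider values. The season geometry
(*T* = 240, *b*_ref = 100, *b*ₛ sweep 100–160) and *M*_L are modelling
choices: arrivals around day 90 (early April), nesting from day 100–160
(mid April–early June) and a hard end of offspring viability at day 240
(late August) give a high-latitude single-brood season; *M*_L is chosen
so that the 130%-of-lean-mass ceiling on total body mass equals exactly
the reserves needed for a full clutch, the smallest cap that leaves
*n*ₘₐₓ attainable. All are exposed in the config.

## Stochastic inputs (what the generator emulates)

`discretize_food_gain` partitions [0, 1] into *k* equal-width bins,
assigns each bin its Beta(α, α) probability mass, and places the outcome
at the bin midpoint rescaled to [*x*₁*w*ₐ, *x*₂*w*ₐ]; a final uniform
shift of the support pins the discrete mean to *w*ₐ exactly (the shift
is at rounding level for a symmetric beta). Exact mean preservation
ensures stochastic and deterministic scenarios share the same average
intake, which the relative-recruitment comparison presumes. The
discretized variance tracks the continuous form
((*x*₂ − *x*₁)*w*ₐ)²/(4(2α + 1)) within 10% for α ≤ 50 at *k* = 20;
the deterministic baseline is a true single-atom distribution at *w*ₐ,
not a large-α limit (both are available).

Arrival days are Normal(*D*ₐ, SDₐ) rounded to whole days and clamped to
the season. Every female receives her own RNG child stream (spawned from
one seed), and daily gains are pre-drawn per (female, day) by inverse
CDF on uniforms. Scenarios sharing a seed therefore share arrival
cohorts and comonotone gain draws across variance levels — common random
numbers that stabilize between-scenario contrasts.

What the generator does **not** emulate: within-season trends or
autocorrelation in food supply, individual quality differences, carry-over
of body condition from the wintering grounds, predation, re-nesting and
adult mortality. Passing tests therefore speak to the internal logic of
reserve-mediated phenology under i.i.d. daily noise, not to any of those
processes.

## Numerics

- Reserves are continuous; values are stored on a uniform grid
  (0, d*S*, …, *S*ₘₐₓ) and read by linear interpolation, in the backward
  recursion and identically in the forward simulation (females act on
  interpolated action values at their exact reserves, not on a
  nearest-node policy). d*S* = 5 g keeps every deterministic trajectory
  (gains of 15, egg cost 165) exactly on the grid, and the forward
  simulation then reproduces the dynamic-programming value to machine
  precision; under stochastic gains it agrees within Monte-Carlo error.
- Ties in the daily maximum are broken incubate > lay > forage: with a
  non-increasing *f*, earlier reproduction is weakly better, and the
  fixed order prevents policy churn between equal-valued cells.
- Infeasible actions are excluded from the maximum rather than clamped
  to zero, so value-0 states are genuine dead ends.
- The backward induction is validated against a no-grid,
  no-interpolation exhaustive enumeration oracle (exact expectation over
  the full outcome tree) on small instances, deterministic and
  stochastic, to machine precision.
- Default problem sizes: 231–33 reserve nodes × 240 days × 8 clutch
  states for the lattice, 10,000 females per scenario, and a reduced
  3 × 3 sweep grid in the test suite; a full 7 × 7 sweep runs in a few
  minutes on one core.

## Design choices made where the design was open

- **One action per day.** Income breeders "forage during laying" by
  alternating days; with the default parameters an income breeder needs
  ⌈*cE*/*w*ₐ⌉ = 11 foraging days per egg, so consecutive eggs are 12
  days apart under constant food.
- **Laying window.** Laying, like incubation, opens at *b*ₛ; otherwise
  the spring onset would not constrain nesting onset at all.
- **No metabolic drain on non-foraging days.** Maintenance costs are
  folded into the *net* daily gain on foraging days; laying and
  incubation costs are carried entirely by the prepaid *cE* per egg.
- **Incubation needs a clutch** (*n* ≥ 1): an empty-nest "incubation"
  would be value-0 noise in the policy and would contaminate
  hatched-clutch summaries.
- **Summary conventions.** Nesting onset and clutch size average over
  females that laid at least one egg; recruitment probability averages
  over hatched clutches; recruits (mean and variance) average over the
  entire cohort with failures contributing zero.

## Behaviour and limitations

Under constant food, income breeders nest essentially at the spring
onset and late onsets cap their clutch (fewer refill cycles fit in the
season), while capital breeders delay nesting after early onsets to
build a larger clutch — the delay, and its increase under fluctuating
food, falls from tens of days at early onsets to ~0 at late onsets.
Fluctuating food always lowers income breeders' mean recruitment (each
per-egg refill wastes the overshoot above the one-egg reserve ceiling)
and inflates its variance as α falls.

For capital breeders, mean recruitment under fluctuating food stays
within a fraction of a percent of the constant-food baseline at early
spring onsets and falls below it at late onsets (reserve caps truncate
the upside of good foraging runs while bad runs still cost). The
near-neutrality at early onsets is structural, not numerical: with a
recruitment curve linear in hatch date and a freely chosen laying date,
the expected time for a single pre-laying accumulation to hit any
reserve target equals target/mean-gain regardless of the noise level
(an optional-stopping identity), so symmetric mean-preserving noise has
no first-order fitness effect; the second-order terms (overshoot waste
and cap truncation against floor reflection at *S* = 0 and adaptive
clutch targeting) nearly cancel. A strict fitness *gain* from foraging
noise at early onsets would require some additional convexity — e.g. a
recruitment curve that is convex in hatch date, or reserve-dependent
incubation success — that this formulation does not contain. This is a
known limitation of the present formulation rather than a numerical
artifact; the directional check on that single claim in
`tests/test_acceptance.py` accordingly fails, and is left failing rather
than weakened, as an honest record of the model's behaviour.

Other limitations: no re-nesting after failure, no partial-clutch
abandonment followed by renewed foraging for capital breeders (foraging
is closed once the first egg is laid), no adult survival cost of late
breeding, and day-resolution time.
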