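# breedopt

State-dependent life-history optimization of **capital** and **income**
breeding in migratory birds under stochastically fluctuating daily food
gain, with forward Monte-Carlo simulation of arriving cohorts.

The package is written for behavioural and life-history ecologists who
want to explore how the interaction between spring phenology (the first
possible breeding day) and short-term resource uncertainty shapes
nesting onset, clutch size and recruitment. The parameterization follows
the biology of Arctic-breeding sea ducks: common eiders, which finance
egg production and incubation from stored reserves (capital breeding),
and king eiders, which keep foraging through the nesting period (income
breeding).

## The model

A female is described by her energy reserves *S* (g), the day of year
*t*, and the number of eggs laid *n*. Each day she takes one action:

- **forage** — reserves change by a random net daily gain
  *w*ᵢ drawn from a *k*-point discretization of a symmetric
  Beta(α, α) distribution rescaled to [*x*₁*w*ₐ, *x*₂*w*ₐ]
  (defaults: *w*ₐ = 15 g/day, *x*₁ = −1, *x*₂ = 3, *k* = 20); reserves are
  floored at 0 and capped at *S*ₘₐₓ,
- **lay** — costs *cE* grams of reserves (egg mass *E* = 110 g times
  *c* = 1.5, prepaying the incubation surcharge) and adds one egg to the
  clutch (at most *n*ₘₐₓ = 7), allowed from the spring onset *b*ₛ,
- **incubate** — terminal: the clutch hatches *I* = 26 days later and
  yields *n·f*(hatch day) expected recruits, where *f* declines linearly
  from 1 at the earliest spring onset to 0 at the season end *T*.

Capital breeders stop foraging at the first egg and carry a large
reserve cap (*S*ₘₐₓ = *n*ₘₐₓ·*cE* = 1155 g, 30% of lean body mass);
income breeders may forage between laying days but can never hold more
than one egg's cost (*S*ₘₐₓ = *cE* = 165 g). The optimal policy

V(S, t, n) = max{ V_forage, V_lay, V_incubate }

is obtained by backward induction from the season end, with linear
interpolation in *S* (the standard dynamic state variable treatment of a
continuous reserve). A cohort of 10,000 females with Normal(90, 10)
arrival days is then simulated forward under independent daily gain
draws, each female taking the best interpolated action at her current
reserves.

## Worked example

Optimize and simulate one scenario per strategy (spring onset day 100,
strongly fluctuating food, α = 0.5):

```bash
breedopt simulate --strategy capital --alpha 0.5 --bs 100 --seed 1 --out demo_cap
breedopt simulate --strategy income  --alpha 0.5 --bs 100 --seed 1 --out demo_inc
```

prints

```
capital b_s=100 alpha=0.5: mean recruits 2.286 (clutch 5.20, onset b_s+47.8)
income b_s=100 alpha=0.5: mean recruits 2.045 (clutch 4.78, onset b_s+5.7)
```

The capital population delays nesting by ~48 days past the spring onset
to build reserves for a five-egg clutch, while income breeders start
laying within a week of the onset and refill reserves between eggs; the
capital strategy converts the same average food intake into ~12% more
recruits per female in this scenario. `demo_cap/females.csv` holds one
row per simulated female (arrival, first egg, incubation onset, clutch,
hatch day, recruits) and `demo_cap/summary.csv` the population means.

The full factorial sweep over strategies, spring onsets and food-gain
variances (with recruitment expressed relative to the matched
deterministic-food baseline) is:

```bash
breedopt sweep --out results/
```

Equivalent library entry points: `breedopt.run_scenario`,
`breedopt.run_sweep`.

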