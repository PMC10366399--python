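# Methods

## Scope and model

`herdplan` schedules individual beef cattle for slaughter across multiple
processing facilities over a multi-month horizon. The decision core is a
mixed-integer linear program over binary facility assignments
`γ_{a,s,t}`, same-facility indicators `z_{a,b,t}`, precedence indicators
`y_{a,b,t}` and continuous slaughter times `x_{a,t}`, with continuous
serving (`Reqserv_{g,t}`), inventory (`h_{g,t}`), live-sale
(`Remsold_{a,t}`, `Reminv_{a,t}`) and deviation (`α_{a,t}`, `β_{a,t}`)
variables. The objective maximises meat revenue plus live-sale revenue
minus earliness/lateness penalties, holding costs, slaughter costs and a
loss-of-opportunity charge on unmet demand.

Assumptions inherited from the production setting:

* all facilities sit inside the farm gate — no transport of live animals or
  products is modelled;
* the herd is closed (no animals enter during the horizon);
* meat is generic once slaughtered — products differ only in pack size
  (`Prop_g`, lbs of meat per unit), price, production cost, holding cost
  and inventory cap;
* 50% of live body weight is edible (configurable `edible_fraction`);
* growth near maturity is slow enough that a one-month planning time step
  is adequate.

## Time coordinate

Months are fixed at 30 days; each day provides 8 working hours. Period `t`
spans working hours `[(t−1)·240, t·240)`. Slaughter times `x` are
continuous working hours on this timeline; earliness/lateness are converted
to days by dividing by 8; reports map hours to calendar days via
`day = ⌊x/8⌋ + 1`. The big-M constant (default 3000) must exceed the
horizon length in working hours and is validated at instance construction.

## Active sets and the scheduling period

Each animal is instantiated in exactly one scheduling period — the period
containing its expected 22-month maturity. With the case-study herd (90
animals maturing per month, 2 facilities, 7 periods) this yields exactly
7·(2·90·89 + 90·2) = 113,400 binary variables. The slaughter time
`x_{a,t}` is *not* clipped to that period: it ranges over the whole
horizon, with the earliness/lateness penalties anchored to the animal's own
ready/due hours. This keeps the pairwise sequencing structure per cohort
while letting the optimizer slaughter an animal at its (typically earlier)
ready time — which is also what makes the comparison against the
fixed-date batch baseline meaningful. Within `[R, D]` the objective is
indifferent to `x`, so the specific in-window time is solver-chosen; the
savings accounting therefore reports both directions of any timing
difference rather than assuming the optimizer always advances.

## Constraint families and their boundary conventions

* **Separation**: `(x_b − x_a) ≥ (Prt·TWA_a + C)·z_{a,b,t} − M·y_{b,a,t}`
  over ordered pairs of cohort-mates. With the defaults
  (`Prt = 1/1500 h/lb`, `C = 0.2 h`) a 1,200 lb animal occupies its
  facility for exactly one hour.
* **Structure**: `z` symmetric; `y_{a,b} + y_{b,a} ≤ 1`;
  `z ≥ γ_a + γ_b − 1` per facility; at most one slaughter per animal,
  summed over facilities *and* periods (one constraint per animal).
* **Meat balance** (per period, aggregated over products):
  `Σ_g h_{g,t−2} + 0.5·Σ_a TWA_a·(γ-sum over t−1, t, t+1) =
  Σ_g Reqserv_{g,t} + Σ_g h_{g,t}`. Any index outside `1..p` contributes
  zero; initial inventory is zero. Note the equality makes slaughtered
  weight enter up to three period balances — the effective serving capacity
  of an interior period is 1.5× the cohort's edible weight, and every
  balance touched by a slaughter must be able to absorb its share (serving
  or inventory), otherwise the slaughter is forgone. Demand caps
  (`Reqserv ≤ Prop_g·Req`) and inventory caps (`h ≤ INVcap_g`) are imposed
  as variable bounds in the solver and re-checked as explicit families by
  the verifier.
* **Leftovers**: `Remsold_{a,t} = TWA_a·(1 − γ-sum at t−2)` for `t > 2`,
  using only the `t−2` term (not a cumulative sum); closing inventory
  `Reminv_{a,t} = TWA_a·(1 − γ-sum at t)` for the last two periods. The
  conservation identity (sold + closing + slaughtered weight = horizon
  weight) then holds structurally; the verifier still recomputes it.
  Because `Remsold` accrues in several periods for a never-slaughtered
  animal, the net objective effect of the live-sale term is a constant
  minus `Pr_live·TWA` per animal slaughtered early in the horizon — an
  opportunity cost of forfeiting the live sale. Default prices keep meat
  value well above live value.
* **Deviations**: `α ≥ (R − x)/8`, `β ≥ (x − D)/8`, both ≥ 0, made tight
  by positive penalties rather than exact-max reformulations with extra
  binaries (identical optima, smaller model). Solution extraction
  recomputes `α`, `β`, `Remsold` and `Reminv` from `x` and the rounded
  binaries, so reported values satisfy their defining identities exactly.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `intake_coeff` | lbs forage / lb live weight / day | 0.02 | 24 lbs/day at 1,200 lbs |
| `dry_matter_fraction` | — | 0.88 | as-fed to dry-matter conversion (informational) |
| `methane_kg_per_cow_year` | kg/head/yr | 150 | enteric 130 + manure 20 |
| `replacement_heifer_kg_year` | kg/head/yr | 58 | itemised separately, never folded in |
| `edible_fraction` | — | 0.5 | inedible share ≈ 50–60% of live weight |
| ready / due time | months | N(21.5, 0.5) / N(23.0, 0.5), clamped 21–24 | Angus finishing band |
| `maturity` | months | N(22, 0.5) | herd-average target processing age |
| `processing_hours_per_lb`, `cleaning_hours` | h/lb, h | 1/1500, 0.2 | 1 h separation at 1,200 lbs |
| `big_m` | working hours | 3000 | > any horizon used |
| prices, penalties, costs | $ | see `instance.py` | farm-specific; documented package defaults |

The monetary defaults (meat prices ≈ $3/lb with product-specific
production costs, live price $0.25/lb, earliness $30/day, lateness $45/day,
LOC $1/unit, slaughter $50–52/animal, holding $0.05/lb/period) are
illustrative: they are chosen so that slaughtering into demand dominates
live sales, lateness is worse than earliness, and the one-pound minced pack
(P2) carries the highest production cost and is therefore the first product
deprioritised when capacity tightens. The frame-score → mature-weight
table shipped is a monotone synthetic stub spanning 900–1,700 lbs (steers)
and 800–1,600 lbs (heifers) over FS 1–9; production use should supply the
official breed table via `GrowthParameters.fs_weight_table`.

## Synthetic data

`generate_herd` emulates a steady-state operation: exactly `cohort_size`
animals reach their expected maturity in each month of the horizon (the
22-month point is placed uniformly inside the cohort's 30-day period).
Hip heights are Gaussian per sex (σ = 1.5 in) at the standard 5-month
measurement age, tuned so frame scores land around 5 ± 1; draws outside
the weight table's domain are resampled. `generate_demand` draws
Gaussian(mean, sd) per product and period, floors negatives at zero and
rounds to the nearest multiple of ten (the pack size), ties away from
zero. Everything is reproducible bit-for-bit from one integer seed.

What the generator does **not** emulate: seasonal demand structure,
correlated growth within sire lines, measurement error in hip heights,
disease/weather shocks to the finishing window, or real price dynamics.
Passing tests on this data demonstrate the scheduling and accounting
machinery, not field performance of any particular farm.

Clamping the ready-time draw into the 21–24 month band shifts its mean:
the lower clamp sits one standard deviation below the mean, so
E[ready] ≈ 21.54 months rather than 21.50. The test suite checks the
Monte-Carlo mean against the closed-form clamped-normal expectation.

## Numerical choices

* Solver: HiGHS through `scipy.optimize.milp`; default relative MIP gap
  1e-4; single-threaded and deterministic — repeated solves of the same
  instance agree to well below 1e-6.
* Oracle tests fix the gap to 0 and use integer-valued time data, for
  which the continuous-time optimum provably lies on the 1-hour grid the
  exhaustive oracle enumerates.
* The independent verifier flags a violation when it exceeds
  `tol · max(1, scale)`, `tol = 1e-6`, `scale` the largest term magnitude
  in the constraint — absolute for unit-scale rows, relative for rows
  carrying tens of thousands of pounds. Binaries are rounded before
  verification; derived quantities are recomputed from them, so the
  conservation identity is checked at machine precision.
* Rounding ties (x.5 to a multiple of ten) go away from zero; negative
  demand draws are floored before rounding.
* An undefined feed conversion ratio (gain ≤ 0 — the due-time condition)
  raises a typed error instead of returning infinity.
* Infeasible models are diagnosed by family-relaxation probing (re-solving
  with one constraint family removed) when the model is small enough;
  larger models report infeasibility without attribution.

## Problem sizes used in the shipped studies

The full case-study instance (1,980-head herd, 630 animals inside a
7-period horizon, 113,400 binaries) is *built* and its variable census
verified, but routine solved studies use scaled instances: the
demand-variance scenario sweep runs 30 animals/period over 3 periods with
five variance levels (4–20% of a capacity-scaled mean), and the
batch-comparison properties use single-cohort instances of ~6 animals.
These sizes exercise every constraint family while keeping each study in
the seconds-to-minutes range on one CPU.

## Known limitations

* The printed balance equality forces every touched period to absorb a
  slaughter's edible weight; with very tight demand and zero inventory
  caps this can forbid slaughters that a soft (≤) balance would allow.
  The behaviour is intentional (it is what the formulation states) but
  worth knowing when configuring scenarios.
* The per-cohort sequencing structure does not enforce cross-cohort
  facility capacity on the calendar timeline: animals of different
  scheduling periods can, in principle, be assigned overlapping hours at
  one facility.
* Within-window slaughter timing is objective-indifferent; reported
  forage/methane savings versus the batch baseline depend on where the
  solver lands inside each window, and are therefore reported with both
  saved and extra components rather than as one net number.
* `Remsold`'s single-lag definition multiple-counts the live-sale revenue
  of long-unslaughtered animals; defaults keep this from distorting the
  slaughter-versus-sell decision, but extreme live prices would.
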