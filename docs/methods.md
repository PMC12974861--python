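# Methods

## Model

`agridiff` simulates the spread of agricultural knowledge through a closed
farmer population with a discrete-time, two-compartment
susceptible–informed (SI) process. One step is one year. Each year the
susceptible pool `S(t)` loses, and the informed pool `I(t)` gains, the sum
of two contributions:

* **Peer sharing** `a·S·I/P` (frequency-dependent mixing, the default) or
  `a·S·I` (mass action). `a` is the probability that a susceptible–informed
  interaction yields a newly informed farmer, aggregated over a year.
* **Campaign reach** `b·M(t)`: money `M(t)` spent on dissemination in year
  `t` informs `b·M(t)` farmers counted at year `t+1`. `1/b` is the cost per
  newly informed farmer.

The joint increment is capped at `S(t)` before being applied, so
`S(t) + I(t) = P` holds exactly for every parameter combination and `I` is
nondecreasing. There is no recovery, forgetting, birth–death turnover, or
network structure, and no stochasticity anywhere: the model is a
deterministic recurrence. Compartment counts are real-valued; rounding to
whole farmers happens only in reported summaries.

**Mixing normalisation.** With the default `a = 0.0004` and a population
of 100,000, the raw mass-action product `a·S·I` would exceed the whole
population in a single step, which no plausible learning campaign shows.
Frequency-dependent mixing (`a·S·I/P`) keeps the sharing term on the scale
of real diffusion and is the package default; mass action is retained as
an explicit option for small populations and for comparison, and the two
are exactly equivalent under the rescaling `a → a/P` (a property the test
suite asserts).

**Initial informed.** `I(0)` defaults to 1% of the population. This is a
calibrated convention, configurable per scenario: with `I(0) = 0.01·P`
the base scenario reproduces the reference revenue/cost/reach figures
below to within 0.3%, while `I(0) = 0` leaves revenue about 8% low. In
population sweeps `I(0)` scales as the configured *fraction* of each
scanned population.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `population_size` | 100,000 | farmers | target population `P = S(0) + I(0)` |
| `initial_informed_fraction` | 0.01 | — | `I(0)/P` |
| `sharing_rate` (`a`) | 0.0004 | 1/year | peer-sharing coefficient |
| `mixing_mode` | frequency | — | `a·S·I/P` vs `a·S·I` |
| `spend_efficiency` (`b`) | 0.56 | informed/USD | ≈ $1.80 per new informed |
| `campaign_schedule` (`M`) | $10,000 in years 0–2 | USD/year | exogenous campaign budget |
| `adoption_rate` | 0.05478 | — | informed → adopting fraction |
| `annual_income` | 1,177 | USD/year | baseline farmer income |
| `income_gain` | 0.19 | — | proportional income uplift from adoption |
| `production_cost` | 30,000 | USD | one-time content creation ($20,000 base + 20 × $500 per language) |
| `adoption_cost_per_adopter_year` | 12 | USD | recurring cost per adopting farmer |
| `horizon_years` (`T`) | 3 | years | impact period |

The defaults are drawn from the agricultural-learning literature on
digital dissemination (video-based extension content distributed through
online platforms). The adoption rate is kept as the exact product
0.498 × 0.11 = 0.05478 rather than the rounded 5.5%, so that reported
adopter counts (e.g. 548 adopters at the 10% reach milestone of a
100,000-farmer population) come out as the integers conventionally quoted.
For horizons longer than three years the campaign budget is *not*
extended: the schedule is padded with zeros, reflecting a fixed three-year
funding window.

## Economics

Revenue in year `t ≥ 1` is `I(t) · adoption_rate · annual_income ·
income_gain`, i.e. recognised on the end-of-year informed stock; there is
no revenue at year 0. Adoption is persistent: once informed, a farmer
contributes `adoption_rate` of a full adopter's revenue and adoption cost
every subsequent year. Cash out charges the production cost once at year
0, the campaign budget in the year it is spent, and the per-adopter cost
on the current adopting stock. All amounts are nominal USD; no inflation
indexing or discounting is applied other than the IRR itself.

**IRR solver.** The internal rate of return is the smallest root of
`NPV(r) = 0` on `r ∈ (−1, ∞)`, located by a sign scan of NPV over a
logarithmic grid of gross rates `1 + r` spanning `(10⁻⁶, 10⁹)` followed by
bisection in log space to relative tolerance 10⁻¹⁰. Ledgers whose
cashflows never change sign (all-nonnegative or all-nonpositive) have no
IRR and return an undefined sentinel (`None`; `NaN` in vectorised sweeps).
When the cashflow sign pattern admits several roots a
`MultipleIRRWarning` is attached and the smallest root is returned; the
investment-shaped ledgers this package produces (one negative year
followed by nonnegative years) have a single root, where this rule is
exact. The test suite checks the solver against an independent
brute-force fine-grid NPV sign scan on batches of randomly generated
ledgers. A vectorised variant applies the identical bracketing/bisection
to a matrix of ledgers for the population sweeps; a test pins it to the
scalar path.

**Breakeven threshold.** A scanned population clears the 0% IRR threshold
when its IRR is defined and ≥ 0. Undefined IRRs count as below the
threshold, with one deliberate exception: a ledger with no negative flow
and a positive total (nothing invested, something earned) is trivially
profitable and clears the threshold even though no IRR exists. Without
this rule a zero-cost scenario would paradoxically never break even.

## Analysis drivers

* **Sensitivity grid**: one-at-a-time scaling of production cost, campaign
  spend, cost per informed (scales `1/b`, so factor 4 means a four-times
  less efficient campaign), adoption cost, sharing rate, adoption rate,
  annual income and income gain by ¼×, ½×, 1×, 2×, 4×. Every cell is a
  fresh simulation; factor-1 rows reproduce the base summary bit-for-bit.
* **Breakeven scan**: populations on an arithmetic grid (default
  1 to 10,000,000 in steps of 100), each simulated with everything else
  unchanged — initial informed at the configured fraction of the scanned
  population, campaign budget fixed (it is an exogenous budget, not a
  per-capita spend). Reports the first grid point with IRR ≥ 0 and the
  maximum defined IRR; an optional bisection refinement sharpens the
  breakeven between bracketing grid points, but the grid answer is
  canonical.
* **Horizon sweep**: the breakeven scan repeated across impact periods
  (default 3, 5, 10, 15, 30 years), with revenue and adoption costs
  accruing through each horizon.

## Reference reconstruction

With the base defaults the package computes (values printed by the code;
see the README worked example): informed counts 1,000 → 6,600.4 →
12,202.9 → 17,807.1; 10% of the population reached after 1.607 years
(reported as 1.6) with 548 adopters at the milestone; 3-year totals of
$448,494 revenue against $84,066 cost; and an IRR of 219.6%/year. The
published figure this scenario family is usually quoted with is an IRR of
208%; the ≈ 6% gap reflects a cashflow-timing/trajectory convention in the
original analyses that is not documented precisely enough to recover, so
the package documents its achieved value rather than tuning any
convention toward the quoted one. The revenue, cost, reach-time and
adopter figures agree with their quoted counterparts to 0.3% or better.

## Structural properties and known limitations

Two structural facts about this model are worth stating explicitly,
because published breakeven tables for models of this family sometimes
suggest otherwise:

* **Breakeven is affine, not proportional, in production cost.** The
  ledger charges the fixed campaign budget (default $30,000 over three
  years) as well as the production cost, so the breakeven population
  scales with (production + campaign) cost. Exact proportionality to
  production cost alone would require the campaign to be free.
* **Spend efficiency saturates at breakeven scale.** Near the base
  breakeven (≈ 1,800 farmers) a single campaign year's reach `b·M`
  already exceeds the whole susceptible pool, so the clamped increment
  informs everyone in year 1 and any `b` above the saturation point
  yields an identical trajectory: raising `b` from 0.56 to 2.2 does not
  move the breakeven at all. Efficiency gains only matter where the
  population is large relative to `b·M`.

Consequently the sweeps reproduce the *qualitative* regularities of
published breakeven analyses — monotone IRR in population size, strictly
smaller breakevens for longer horizons, near-constant maximum IRR across
horizons, breakevens nondecreasing in production cost and nonincreasing
in `b` — but not their absolute breakeven counts or maximum IRRs, whose
generating conventions are not recoverable (those published counts do not
even lie on the scan grid said to produce them).

Other limitations: the synthetic random-scenario generator draws
parameters independently and uniformly within literature-informed ranges;
it emulates the parameter envelope of real campaigns but not correlations
between parameters (e.g. richer regions having both higher incomes and
higher media reach), heterogeneity within a population, or time-varying
sharing behaviour — so passing property tests demonstrate model
invariants, not forecasting accuracy on real initiatives. The linear
reach model `b·M` ignores diminishing returns to advertising. Annual time
steps make sub-year reporting (such as the 1.6-year reach time) an
interpolation between annual states — the minimal assumption consistent
with fractional-year reporting.

## Problem sizes

The default test suite and the reproduction script run the base scenario
(T = 3, P = 100,000) and population scans of up to 100,000 grid points
(1 to 10,000,000 step 100) at horizons up to 30 years; vectorised
simulation and IRR solving keep every driver to a few seconds on one CPU.
Unit tests use narrower scan windows (up to 60,000 farmers), which bracket
every breakeven they assert about.
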