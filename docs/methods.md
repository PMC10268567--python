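# Methods

## Model structure

The engine is a discrete-time cohort Markov model with monthly cycles and a
5-year (60-cycle) horizon.  One arm = one transition matrix; the three arms
(Optilume, endoscopic management, urethroplasty) share a state template:

- `initial_treatment(arm)` — occupied only at cycle 0; the whole cohort
  moves on after one cycle.
- `cured_after_endo_or_optilume`, `cured_after_urethroplasty` — recurrence
  risk depends on the *last treatment received*: the arm's own monthly
  recurrence probability after an endoscopic-class procedure, the
  urethroplasty probability (0.9%/month in every arm) after a
  urethroplasty.
- `recurrence_awaiting_after_*` — treated recurrences queue here; the exit
  probability per cycle is calibrated to the median time to retreatment.
  On exit the cohort splits between a urethroplasty and a repeat
  endoscopic-class procedure (70/30 after an endoscopic-class procedure,
  12/88 after urethroplasty) and lands in the cured state of the new
  treatment.  Retreatment is instantaneous at the exit transition; the
  episode cost is attached to that transition.
- `recurrence_untreated` — the 10% of recurrences that receive no further
  treatment; absorbing apart from death, and accrues the recurrence state
  cost.
- `dead` — absorbing.  Death competes proportionally with all other exits:
  the monthly death probability is applied first and the remaining mass
  follows the alive kernel.

Costs per cycle: the initial episode (procedure + one-off adverse-event
cost) and, in the Optilume arm, the £8.53 per-patient training cost are
charged at cycle 0 undiscounted; retreatment episodes are charged on their
transition flows at the destination cycle's discount factor; state costs
(£18.33/month cured, £44.74/month in any recurrence state) accrue from
cycle 1 onward on end-of-cycle occupancy.  Discounting is
`(1.035)^(−t/12)` per monthly cycle `t`.  No half-cycle correction is
applied: the cycle is short relative to the horizon and the correction
would be smaller than the structural uncertainties discussed below.  No
state cost accrues during the initial-treatment cycle.

## Parameters and defaults

All inputs live in one flat YAML file
(`src/stricture_econ/data/defaults.yaml`); `load_parameters`
validates every field and reports *all* violations at once.  Key defaults:

| Parameter | Default | Note |
|---|---|---|
| monthly recurrence: endoscopic / Optilume | 0.163 / 0.026 | from 88.1% / 26.9% 12-month risks (ROBUST III), constant hazard |
| monthly recurrence: urethroplasty | 0.009 | OPEN RCT, 24-month outcome |
| treated after recurrence | 0.90 | remainder stay untreated |
| retreatment splits | 70/30 and 12/88 | by last treatment |
| median wait to retreatment | 47.5 d / 90 d | endoscopic-class / urethroplasty queues |
| episode costs | £1196, £4761, £1986 | endoscopic, urethroplasty, Optilume incl. device |
| adverse-event costs | £63.40, £17.46, £15.16 | one-off per episode |
| state costs | £18.33 / £44.74 per month | cured / recurrence |
| discount rate (costs) | 3.5%/year | |
| horizon | 60 cycles of 1 month | |
| days per month | 30.4375 | 365.25/12, configurable |
| monthly death probability | 0 | see below |

Derived quantities: the recurrence-queue exit probabilities are 0.3586
(47.5 d) and 0.2090 (90 d); a repeat in the Optilume arm is charged at the
full device-inclusive Optilume episode (£2001.16); the optional
pre-dilation cost (£20.36) is off by default because the device-inclusive
episode price already reproduces the intended initial-episode total
(£1986 + £15.16 → £2001) without it.

**Background mortality defaults to zero.**  Annual all-cause mortality for
men around age 59 is roughly 1%, which over five years shifts every arm
total down by under 2% and the incremental by less, while a defensible
life-table source would add configuration surface without changing any
conclusion.  Reconstructing the occupancy implied by published totals for
this model class also points to death being negligible in practice.  A
constant `monthly_p_death` can be set in the config and all machinery
(competing exits, absorbing dead state) is exercised by the tests.

**Recurrence-queue exits.**  The default is a memoryless geometric exit
whose *median* matches the observed median wait — the natural reading of
"time in the state depends on the median time to treatment" for a Markov
model.  An alternative `fixed_tunnel` mode holds patients for exactly
`round(median/days_per_month)` cycles (2 and 3 cycles) via tunnel
sub-states; it exists because the choice is structural, not estimable from
the inputs, and it matters (see limitations).

## Sensitivity analyses

Every clinical and cost input is uncertain except the discount rate, horizon
and mortality: three recurrence probabilities, treatment uptake, the two
retreatment splits (sampled as one beta draw with its complement, so each
pair keeps summing to 1), the two queue-exit probabilities (applied by
inverting back to a median), and nine costs.  Probabilities get
moment-matched beta distributions, costs gamma, with SE = 25% of the mean
when no confidence interval is supplied.  The PSA (default 1000
iterations, mandatory seed, `numpy` `default_rng`) redraws every parameter
independently per iteration, reruns the full two-arm comparison and
reports the fraction of draws with negative incremental cost.  The DSA
sets one parameter at a time to the 2.5th/97.5th percentile of the same
distribution and orders parameters by the absolute range of the
incremental cost (tornado order); `sign_flip_parameters` lists those whose
bounds disagree in sign with each other or the base case.

A caveat worth knowing: the 25%-of-mean rule applied to a probability with
mean 0.9 (treatment uptake) yields a very heavy-tailed beta whose 2.5th
percentile is ≈0.10, so that parameter dominates the tornado's lower tail.
That is a property of the reconstruction rule, not of the engine; supply a
`ci` to `build_distribution` to narrow it.

## Synthetic data and what it shows

`synthetic.simulate_trial_arm` draws *discrete geometric* recurrence months
— exactly the engine's monthly kernel, deliberately not a continuous
exponential — so parameter-recovery tests are free of discretisation bias.
It emulates only the cumulative-recurrence structure the model consumes,
not trial endpoints (no IPSS responder definitions, covariates, dropout or
reporting asymmetries), so passing recovery tests shows the conversion
pipeline is self-consistent, not that the trial estimates themselves are
unbiased.

`synthetic.microsim_cohort` is an independent oracle: it samples individual
patient paths directly from the arm's transition matrix and accrues the
same costs patient-by-patient, never touching the cohort trace.  Cohort
engine and microsimulation agree within Monte-Carlo error (3 SE at
n = 50 000, per category and in total) — a strong check that the matrix
algebra and the reward accounting mean what they claim.

`synthetic.random_parameter_set` generates valid random configurations
(probabilities in (0, 0.5), costs in (0, 10 000), splits summing to 1) for
property sweeps such as mass conservation.

## Numerical choices

- Row-stochasticity enforced to 1e-12 at matrix construction, with the
  offending row named on failure; trace conservation asserted to 1e-10.
- Beta/gamma moment matching is closed-form, so (mean, SE) are recovered
  exactly; sampling uses `numpy`'s generators, percentiles use `scipy`.
- Degenerate inputs are first-class: zero risks give the discounted-annuity
  closed form to 1e-6; certain death empties every alive row; zero-mean
  costs become fixed (degenerate) distributions with zero tornado range.
- Whole-GBP rounding (half away from zero) happens only in markdown
  presentation tables; CSV/JSON outputs carry full precision.
- Problem sizes: 1000 PSA iterations (the conventional stability point for
  this model; ~3 s), 50 000 microsimulation patients (oracle SE ≈ £13).

## Known limitations

- Cost-consequence only: no utilities, QALYs, ICERs or acceptability
  curves.
- Efficacy is assumed identical for initial and repeat procedures, and
  recurrence memory extends only to the last treatment class.
- Mortality is a constant monthly probability (default 0), not an
  age-interpolated life table.
- Published totals for models of this kind are sensitive to structural
  conventions that inputs alone do not pin down — how long recurrences wait
  before retreatment, whether untreated recurrences keep accruing follow-up
  costs, and how much post-urethroplasty cycling occurs.  With the inputs
  above, the base case yields £6441 (Optilume) vs £8087 (endoscopic), a
  £1646 saving, and £6618 for the urethroplasty comparator (£176 saving);
  plausible alternative conventions move the comparator totals by several
  hundred pounds but not the sign or ordering of the arms, and the PSA
  cost-saving fraction stays above 90%.
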