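# stricture-econ

A cohort Markov cost model comparing managements of **recurrent anterior
male urethral stricture** from the NHS England perspective: the Optilume
paclitaxel drug-coated balloon versus endoscopic management (urethral
dilation / direct-vision internal urethrotomy) in the base case, and versus
urethroplasty in a scenario analysis.  The package is for health economists
and methodologists who want a tested, scriptable reimplementation of this
kind of decision model — every input is a plain YAML key, every analysis is
a library call, and an independent patient-level microsimulation oracle
cross-checks the cohort engine.

## The model

A closed cohort of men (starting age 59) enters an initial-treatment state
and moves through monthly cycles over a 5-year horizon (60 cycles).  The
health states are: initial treatment; cured after an endoscopic-class
procedure; cured after urethroplasty; recurrence awaiting retreatment
(separate queues by last treatment); untreated recurrence; and death
(absorbing, reachable from every state).

Per-cycle recurrence probabilities are derived from trial-reported
cumulative risks under a constant hazard,

```
p = 1 − (1 − R)^(1/T)
```

so the 12-month recurrence risks of 88.1% (endoscopic, ROBUST III) and
26.9% (Optilume) become monthly probabilities of 16.3% and 2.6%; recurrence
after urethroplasty is 0.9%/month (OPEN RCT, from the 24-month outcome).
Of recurrences, 90% are treated: after an endoscopic-class procedure the
retreatment splits 70% urethroplasty / 30% repeat endoscopic-class (a
repeat in the Optilume arm is another Optilume at full device-inclusive
price); after urethroplasty it splits 12% / 88%.  The wait in the
recurrence queue is geometric with its per-cycle exit probability
calibrated to the median time to retreatment (47.5 days endoscopic-class,
90 days urethroplasty):

```
p_exit = 1 − 0.5^(days_per_month / median_days)
```

Costs (GBP, 2019/20) are NHS reference costs and manufacturer prices:
procedure episodes (procedure + one-off 30-day adverse-event cost) are
charged on the retreatment transitions, monthly state costs accrue in the
cured (£18.33) and recurrence (£44.74) states, and costs are discounted at
3.5% per year.  The primary outcome is the **incremental mean discounted
cost per patient** (negative = Optilume saves money); there are no QALYs in
this model.

Uncertainty is propagated two ways: a probabilistic sensitivity analysis
(1000 iterations; moment-matched beta distributions for probabilities,
gamma for costs, SE = 25% of the mean) and a one-way deterministic
sensitivity analysis at the 2.5th/97.5th percentiles, summarized as a
tornado table.

## Worked example

```bash
stricture-econ base-case --out demo --format all
```

```
INFO stricture_econ: base case: optilume £6441.49 vs endoscopic £8087.18 (incremental £-1645.69)
```

and `demo/base_case.md` holds the rounded presentation table:

| Category | optilume | endoscopic | incremental |
|---|---|---|---|
| initial_procedure | £2001 | £1259 | £742 |
| repeat_endoscopic | £637 | £778 | £-141 |
| repeat_urethroplasty | £2630 | £4713 | £-2082 |
| training | £9 | £0 | £9 |
| cured_state | £901 | £781 | £120 |
| recurrence_state | £263 | £557 | £-293 |
| total | £6441 | £8087 | £-1646 |

Reading it: Optilume's initial episode costs £742 more per patient
(device-inclusive £2001 vs £1259) but its far lower recurrence rate avoids
most of the comparator's repeat procedures — above all repeat
urethroplasties (−£2082) — so over five years Optilume saves £1646 per
patient.  The probabilistic sensitivity analysis

```bash
stricture-econ psa --out demo --seed 1 --iterations 1000
```

reports `"fraction_cost_saving": 0.91`: Optilume remains cost saving in 91%
of draws from the joint parameter distribution.  `stricture-econ scenario`
and `stricture-econ dsa` produce the urethroplasty comparison and the
tornado table the same way.  The same results are available as library
calls (`base_case`, `scenario_urethroplasty`, `run_psa`, `run_dsa` on a
`ParameterSet` from `default_parameters()` or `load_parameters(path)`).

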