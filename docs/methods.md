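# Methods

## Model structure and assumptions

The model is a deterministic cohort pathway model. A cohort of
consultation requests flows through one of two arrangements and every
branch contributes expected GP minutes per request; the output is the
ratio of digital-first to conventional workload, expressed as a percent
change. The model's scope is deliberately narrow:

* Only GP time is counted. Effects on nurses, pharmacists, receptionists
  and emergency departments are out of scope.
* The cascade stops after the immediate follow-up: a f2f consultation that
  results from a digital contact is counted, later follow-up consultations
  are not.
* Requests are homogeneous: every request faces the same branch
  probabilities and every consultation of a given type has the same
  duration. The model is linear in the durations, so means are sufficient;
  heterogeneity would change variances, not expected workload.
* Demand inflation is a fixed point: if a fraction `d` of digital
  consultations are new supply-related demand and the digital route takes
  a share `a` of all requests, total requests per baseline request are
  `N = 1 + d·a·N`, i.e. `1/(1 − d·a)`. The model requires `d·a < 1`;
  `d·a ≥ 1` (self-amplifying demand) is rejected as a domain error.

One structural choice deserves emphasis: **all telephone contacts share
one set of cascade parameters** — completion rate `c_p` and duration
`t_p` — whether the contact is the conventional arm's telephone
consultation, the telephone-first contact, or a phone follow-up after an
e-consultation. For the telephone-first pathway this means the pathway's
own completion rate and call duration *are* the shared cascade
parameters, so perturbing either (in sweeps, bound cases, random
scenarios, or the break-even solver) moves both the digital arm and the
conventional comparator's telephone arm. There is one kind of telephone
consultation in the model, and the comparator is not frozen at base
values when telephone parameters are explored.

## Parameters

All rates are stored as fractions in [0, 1]; durations are minutes.
Config files and the printed catalog use percentages (`_pct` fields) and
convert on load.

| Parameter | Meaning | Base (econsult / telephone / video) |
|---|---|---|
| `access_rate` | share of requests entering the digital pathway first | 0.90 / 0.93 / 0.90 |
| `completion_rate` | share of digital contacts resolved with no follow-up | 0.30 / 0.52 / 0.65 |
| `phone_followup_fraction` | share of e-consultation follow-ups done by phone | 0.46 / — / — |
| `digital_duration` | GP minutes per digital contact | 4 / 5 / 9 |
| `demand_fraction` | share of digital consultations that are new demand | 0.10 / 0 / 0 |

The conventional mix is fixed at 86% f2f (9 min) / 14% telephone, and the
shared phone cascade at completion 0.52, 5 min. Each pathway variable
carries lower/upper bounds (encoded with provenance notes in
`src/gpworkload/data/table1.yaml`) spanning the plausible range from
outlier studies and informed judgement; the telephone follow-up split is
structurally absent, not zero, outside the e-consultation pathway.
`demand_fraction` lives in the open interval (−1, 1): negative values
model a digital route that suppresses demand, and the multiplier formula
applies unchanged.

The demand fraction can also be estimated from routine monthly counts as
`(contacts_after − contacts_before − duplicates) / digital_consultations`,
where duplicates are f2f consultations directly caused by a digital one;
`estimate_supply_related_demand` implements this and may return negative
values.

## Numerical choices

* **Rounding.** Headline results are reported both unrounded and rounded
  half-up to integer percent (`floor(x + 0.5)`, halves toward +∞).
* **Break-even.** Bisection on percent change with default tolerance
  1e−9 and a 200-iteration cap. Closed-form roots exist for each variable
  separately, but bisection keeps one solver generic across all of them.
  A coarse 17-point scan of the bracket flags non-monotone behaviour as a
  warning in the result metadata rather than an error, since bisection
  still returns one valid root.
* **Sweeps.** Grid cells that leave the model domain (`d·a ≥ 1`, possible
  only with user-supplied grids) become missing values (empty CSV fields)
  instead of aborting the sweep. Default grids: rates 0–100% in steps of
  5, durations {4, 5, 6} min, demand −10%–30% in steps of 2.
* **Degenerate inputs.** Zero or negative durations are validation
  errors, not free consultations; proportions outside [0, 1] and mixes
  not summing to 1 (tolerance 1e−12) are rejected with the offending
  field named. Config validation reports every invalid field at once.
* **Serialization.** Percentages are rounded to 10 decimals when
  serializing so that fraction→percent→fraction round-trips are exact for
  catalog values and accurate to ~1e−13 otherwise.

## Microsimulation oracle

`simulate_cohort` re-derives the workload change by simulating individual
requests: the baseline cohort is inflated *deterministically* by the
demand multiplier (so the oracle isolates branching variance rather than
mixing in demand randomness), and every branch point — access, digital
completion, follow-up modality, each phone cascade — is an independent
Bernoulli draw. The empirical percent change comes with a standard error
derived from the per-request minute variance; the generator is seeded
explicitly, with no global random state. Because the closed form is the
exact expectation of the simulated process, agreement within a few
standard errors on randomly drawn scenarios is a strong end-to-end check
of both implementations; the test suite checks 50 random scenarios at one
million baseline requests each against a 3-standard-error band, with
frozen seeds so the check is reproducible. Random test scenarios are
drawn uniformly within the catalog lower–upper ranges, which keeps them
in the parameter region the model is meant for (demand at most 0.30, so
`d·a < 1` always holds).

What passing these tests shows — and does not show. The microsimulation
validates the algebra of the pathway cascade, not the realism of its
inputs: it emulates the same homogeneous-cohort, one-step-cascade world
as the closed form. Agreement says nothing about patient heterogeneity,
day-to-day demand dynamics, or behavioural responses (e.g. clinicians
lowering their completion threshold under load), none of which the model
represents.

## Known limitations

* The comparator's telephone share (14%) is held fixed; a practice that
  already does substantial telephone triage would need a custom
  conventional mix via the config file.
* Supply-related demand enters as a single static fraction; the model has
  no time dimension, so transient demand surges and 28-day compensatory
  consultation effects are invisible to it.
* Costs, quality, safety and equity are outside the model: it prices
  everything in GP minutes only.
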