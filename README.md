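# gpworkload

A deterministic decision model of general-practice (GP) workload under
**digital-first access pathways**: arrangements where a patient's first
contact with a practice is an online e-consultation form, a telephone call,
or a video consultation, with a face-to-face (f2f) consultation only when
the first contact does not resolve the problem. The package is for health
services researchers and planners who want to test, under their own
assumptions, whether such pathways save or cost GP time compared with
conventional, predominantly face-to-face care.

## The model

Workload is GP minutes per consultation request. Conventional care sees a
fraction *f* of requests face-to-face (duration *T<sub>f</sub>*) and the
rest by telephone; a telephone contact costs *t<sub>p</sub>* minutes and
cascades to f2f with probability 1 − *c<sub>p</sub>*, where *c<sub>p</sub>*
is the telephone completion rate:

```
W_conv = f·T_f + (1 − f)·(t_p + (1 − c_p)·T_f)
```

Under a digital-first pathway a fraction *a* (the **access rate**) of
requests start digitally, at *t* minutes each; a fraction *c* (the
**completion rate**) need nothing further, the rest cascade to a follow-up.
After an e-consultation the follow-up is a telephone call with probability
*p* (which can itself cascade to f2f) or a direct f2f consultation; after
a telephone-first or video-first contact it is f2f:

```
E_digital = t + (1 − c)·T_f                                      (telephone, video)
E_digital = t + (1 − c)·[ p·(t_p + (1 − c_p)·T_f) + (1 − p)·T_f ]  (e-consultation)
```

Easier access can change demand itself: if a fraction *d* of digital
consultations are **supply-related demand** (requests that would not exist
under conventional care; *d* may be negative), total requests per baseline
request are `1 / (1 − d·a)`. The headline output is

```
percent change = 100 · ( [a·E_digital + (1 − a)·W_conv] / (W_conv·(1 − d·a)) − 1 )
```

so +10 means 10% more GP hours than conventional care. Every telephone
contact in the model — conventional-arm, telephone-first, or a phone
follow-up after an e-consultation — carries the same cascade parameters
(*c<sub>p</sub>*, *t<sub>p</sub>*).

The package ships a catalog of evidence-based base-case values with
plausible lower/upper bounds for each pathway, one-way/two-way sensitivity
sweeps, tornado analysis, a bisection break-even solver, and a
Bernoulli-branching microsimulation that serves as an independent check on
the closed form.

## Worked example

```python
>>> import gpworkload as gw
>>> for kind in ("econsult", "telephone", "video"):
...     r = gw.workload_change(gw.base_case(kind))
...     print(kind, round(r.percent_change, 2), r.rounded_percent_change)
econsult 24.74 25
telephone 2.83 3
video 30.9 31
```

With base-case assumptions, an e-consultation-first model increases GP
workload by about 25% (short 4-minute reviews are outweighed by a 30%
completion rate and 10% new demand), telephone-first by about 3%, and
video-first by about 31% (video calls are as long as f2f but still cascade).

The break-even solver finds the completion rate at which telephone-first
stops costing time, with 5-minute calls and no change in demand:

```python
>>> s = gw.with_param(gw.base_case("telephone"), "demand_fraction", 0.0)
>>> gw.break_even(s, "completion_rate", 0.0, 1.0).value
0.5555555555620231
```

i.e. at least 55–56% of calls must be completed without a f2f follow-up.

The same runs from the shell:

```
$ gp-workload run --preset telephone-base          # JSON, rounded_percent_change: 3
$ gp-workload breakeven --preset telephone-base --var completion_rate --lo 0 --hi 1
0.555556
$ gp-workload sweep --preset econsult-base --var demand_fraction --out sweep.csv
$ gp-workload estimate-demand --before 1000 --after 1100 --duplicates 40 --digital 600
0.100000
```

Scenarios can also come from a YAML/JSON config file (`--config`); rate
fields end in `_pct` and are percentages — see `gpworkload/io.py` for the
schema, and `docs/methods.md` for parameter definitions and defaults.

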