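# ocudelay

Health-economic model of **delayed (or expedited) eye care**: the societal
cost and quality-of-life impact, per patient per period of delay, of
postponing elective ophthalmic follow-up — with cohort-level aggregation
over a triage-decision mix and a seeded synthetic cohort generator.

It is written for health economists and eye-care service evaluators who
need a transparent, parameterised cost-consequence model of remote triage:
when a tele-triage service postpones some appointments to free capacity
for more urgent patients, what does 6 months of delay cost society per
delayed patient, what is gained per expedited patient, and how do the two
balance at cohort scale?

## The model

For a diagnosis *d*, the societal cost of a 6-month delay is the sum of
four components (EUR, negative = saving):

```
C_d = ΔM_d  +  P_d  +  I_d  +  E_d

P_d = w · h · W_p · λ · e · f_d · κ_d        (productivity, human capital)
I_d = g · r · W_c · κ'_d                     (informal care)
E_d = p_d · Σ_{j ∈ bundle_d} u_j             (expected missed-event cost)
```

where `w` is the hourly wage, `h` the average workweek, `W_p` the working
weeks per half year (23.5 = 47/2), `λ` the productivity reduction with
vision loss, `e` the employed labour-force fraction, `f_d` the share of
patients of working age, `W_c` the 26 calendar weeks of a half year,
`g`·`r` the weekly informal-care hours and shadow rate, `p_d` the
probability of a missed clinical event per 6 months of delay, and `u_j`
the unit costs of the care bundle the event triggers.  The conditioning
factors `κ_d, κ'_d` encode the diagnosis's **inclusion policy**: for
symptomatic disease (cataract, dry eye) societal costs accrue over the
whole delay (`κ = 1`); for stable disease (AMD, DRP, glaucoma) they accrue
only when an event is missed (`κ = p_d`).

The QALY loss is the utility decrement `Δu_d` directly (symptomatic) or
`Δu_d · p_d` (stable).  Quantities with published upper/lower bounds are
carried as intervals and propagated bound-wise; all arithmetic is full
precision, rounded only for display.  Other durations scale linearly, and
negative durations model **expedited** care as the mirror image of delay.

The package also implements the *medical basket approach* for moving
literature costs to Dutch 2023 euros (CPI inflation within the source
economy, then hospital-services PPP conversion), and ships the Dutch 2023
default parameter set for the five key diagnoses.

## Worked example

```python
>>> from ocudelay import default_parameters, societal_delay_cost
>>> constants, profiles = default_parameters()
>>> amd = {p.name: p for p in profiles}["amd"]
>>> impact = societal_delay_cost(amd, constants)
>>> impact.societal_cost_total
Interval(lower=1373.1719024580832, upper=1454.9419024580834)
>>> impact.qaly_loss
Interval(lower=0.05605, upper=0.05605)
```

Delaying one stable AMD patient by 6 months saves €581–663 of injections
and scans but is expected to cost €87 in lost productivity, €1673 in
informal care and €277 in missed-event care — a net societal cost of
€1373–1455 and 0.056 QALYs lost.  The full worksheet:

```bash
$ ocudelay table --which breakdown
diagnosis,medical_cost,...,societal_cost_total
cataract,0.0,...,3298.42
des,-423.91,...,2155.74
amd (upper),-581.32,...,1454.94
amd (lower),-663.09,...,1373.17
drp,-85.84,...,117.28
glaucoma,-408.78,...,-408.65
```

Only stable glaucoma nets out as a saving (−€409); cataract is costliest
(€3298) because its patients wait symptomatic for the whole delay.  The
`examples/` directory holds short narrative scripts for each capability
(per-patient costs, QALY losses, currency updating, cohort trade-off);
each prints its results with a line on what they mean.

## Layout

- `src/ocudelay/parameters.py` — domain types, Dutch 2023 defaults, YAML config I/O
- `src/ocudelay/cost_model.py` — the four cost components, totals, duration scaling
- `src/ocudelay/qaly_model.py` — QALY losses (both readings of an inconsistent source figure)
- `src/ocudelay/currency.py` — CPI/PPP cost updating
- `src/ocudelay/cohort.py` — cohort aggregation and the delay/expedite trade-off
- `src/ocudelay/synthetic.py` — seeded synthetic triage cohorts
- `src/ocudelay/tables.py`, `cli.py` — publication-style tables, thin CLI
- `docs/methods.md` — modelling assumptions, parameter provenance, limitations
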