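# Methods

## Scope and model structure

`ocudelay` is a deterministic cost-consequence model: it presents the
costs and health outcomes of delaying elective ophthalmic care as
disaggregated components rather than collapsing them into a single
cost-effectiveness ratio.  The unit of analysis is one patient of one
diagnosis delayed (or expedited) for a given number of months; cohort
results are sums of per-patient results.  There is no discounting (the
horizon is at most a year), no patient-level heterogeneity in wages or
visual acuity, and no queueing or capacity simulation of the clinic.

## Cost components and their assumptions

**Medical cost delta** (`medical_cost_delta_semester`, EUR/patient/6
months).  Taken directly from the per-diagnosis parameter: the change in
direct medical spending when care is postponed.  Negative values are
savings (consultations, scans, injections not delivered during the
delay).  Cataract's delta is zero by construction — surgery is delayed,
not avoided, so its cost is not saved; this is encoded in the default
profile, not special-cased in code.

**Productivity cost** (human capital approach).  A working-age, employed
patient with untreated vision loss produces less paid work.  The base
semester value is

    wage/h × workweek h × working weeks per half year
           × productivity-loss fraction × employed labour-force fraction

(defaults 39.88 × 32.2 × 23.5 × 0.2058 × 0.7039 ≈ €4371.55), multiplied by
the diagnosis's working-population share and its conditioning factor.
Working weeks per half year are 23.5 (47 working weeks per year / 2).

**Informal care cost.**  Unpaid caregiver time valued at a shadow price:
5.8 h/week × €18.80/h over the **26 calendar weeks** of a half year
(≈ €2835.04), times the conditioning factor.  Note the two week counts
are deliberately different: paid work stops during holidays, informal
care does not.

**Expected missed-event cost.**  During a delay an adverse event
(choroidal neovascularisation, macular oedema, acute angle closure) may
go undetected; its expected cost is the event probability times the
priced bundle of care it triggers (e.g. consultation + OCT + intravitreal
injection for CNV/MO; consultation + OCT + iridotomy laser + medication
for acute glaucoma).

**Inclusion policies.**  Four behaviours cover every default diagnosis:
`full` (productivity and informal care accrue unconditionally —
symptomatic cataract), `productivity_only` (dry eye: informal care is
zero in the defaults because no estimate exists; shipped as structurally
zero), `event_conditional` (stable AMD/DRP/glaucoma: both accrue only
with the missed-event probability), and `none` (neither).

## QALY model

Utilities run 0 (death) to 1 (perfect health); a QALY loss of 0.1 is
roughly half a month of perfect health.  Symptomatic diagnoses take the
utility decrement itself as the 6-month QALY difference — the convention
of the published figures this model reproduces.  The alternative reading
(decrement × 0.5 years) would halve those numbers; it is deliberately not
the default because the published per-6-month figures are the model's
reference surface.  Stable diagnoses weight the decrement by the
missed-event probability.

The glaucoma source figures are internally inconsistent: the cost cells
use an event probability of 3.1 × 10⁻⁵ (a printed "0.0031%"), while the
published QALY of 0.00031 requires 0.0031.  Rather than silently picking
one reading, profiles may carry a `reported_qaly_event_probability` used
only in `as_printed` mode; `internally_consistent` mode uses the same
probability as the cost model (giving 3.1 × 10⁻⁶ for glaucoma).

## Duration scaling and the expedite symmetry

Results are defined per 6 months (the service's average delay).  Other
durations scale linearly — costs and QALY losses accrue at a constant
rate — which is the minimal assumption consistent with per-period
reporting and is documented as replaceable.  Expedited care (negative
months) is the exact negation of delay harm.  This is a strong symmetry
assumption: the published account argues qualitatively that earlier
treatment has the "opposite effect" but never quantifies the gain, so the
package surfaces the assumption instead of hiding it.

## Currency updating

Costs move between years and countries by (1) CPI inflation inside the
source economy, then (2) hospital-services-basket PPP conversion at the
target year.  The order of the two steps is not dictated by the method;
`inflate_first` is the default and `convert_first` (PPP at the source
year, then target-country CPI) is available behind a flag, since the two
differ whenever PPP factors move over time.  Index tables are
user-supplied CSVs; missing (country, year) entries raise an error and
are never interpolated.  The shipped defaults are already Dutch 2023
euros, so no index data ships with the package.

## Cohort aggregation

Each delayed/expedited record contributes its diagnosis's 6-month impact
scaled to its own delay; records triaged to referral, cancellation,
teleconsultation, "other" or an unchanged consultation contribute zero,
because no delay parameters exist for those pathways — even though such
patients plausibly also experience delay.  A
`decision_delay_overrides` hook assigns them a delay-equivalent duration
for sensitivity exploration; overrides feed the totals but not the
delayed-vs-expedited net trade-off, which keeps the trade-off's meaning
fixed.

## Synthetic cohort generator

The generator emulates the *structure* of a real tele-triage cohort of
3658 re-triaged appointments: decision mix 51% unchanged, 20% delayed,
13% referred, 6% cancelled, 4% teleconsultation, 1% expedited, 5% other;
delays of 6 ± 4 months.  It does **not** emulate demographics, visual
acuity, triage accuracy, or any per-patient correlation between diagnosis
and decision — passing cohort-level tests therefore shows the accounting
is right, not that real-world triage behaves this way.

Delay durations are drawn from a normal distribution truncated below at a
minimum delay (default 1 month; a realised delay cannot be ≤ 0) and
rounded to whole months.  The truncated distribution is
**moment-matched**: location and scale are solved numerically so the
truncated mean and standard deviation equal the requested 6 and 4.  A
normal(6, 4) naively truncated at 1 would have mean ≈ 6.8; since the
published 6 ± 4 describes the realised, necessarily positive delays,
matching the truncated moments is the faithful choice.  Rounding to whole
months perturbs the moments by well under the sampling noise at the
tested sizes.  The uniform default diagnosis mix over the five key
diagnoses is a placeholder — the true per-diagnosis composition of the
delayed group is not published — and is user-overridable.

## Numerical conventions

- All accumulation is double precision; components are summed unrounded.
  This is forced by the published worksheet itself: the glaucoma societal
  total −408.65 emerges only from unrounded components (rounding each to
  cents first gives −408.64).
- Display rounding is half-up (ties away from zero) to the cent, via
  `decimal`.
- Interval quantities (AMD's medical bounds, cataract's utility range)
  propagate bound-wise through sums and flip bounds under negative
  scaling, so every stored interval keeps lower ≤ upper.
- One published labelling oddity is reproduced, not reinterpreted: the
  AMD row labelled "upper limit" carries the smaller saving (−581.32) and
  hence the larger societal total (1454.94).

## Problem sizes used in the test suite

Property tests draw 100–1000 random parameter sets; generator convergence
is checked on one cohort of 100 000 patients (decision fractions within
±0.005–0.01, delay mean within ±0.1 months); the cohort-scale consistency
check runs the service-sized cohort of 3658 patients and compares the
summed delayed-patient cost with its analytic expectation within four
analytically derived standard errors.  These sizes make the whole suite
run in a few seconds while holding Monte-Carlo noise well below the
tested tolerances.

## Known limitations

- Linear duration scaling and the delay/expedite symmetry are modelling
  conveniences, not evidence-based dose-response curves.
- Referred/cancelled/remote pathways are zero-cost by default although
  they likely carry delay in reality.
- The defaults are a Dutch 2023 transcription; applying the model
  elsewhere requires re-deriving the parameter set (the currency module
  helps, but working-population shares, event probabilities and unit
  costs are country-specific).
- Event probabilities and utility decrements are literature point
  estimates; no probabilistic sensitivity analysis is built in, though
  the parameter objects make one straightforward to script.
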