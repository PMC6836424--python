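# Methods

This note records the model implemented by `pumpwatch`, the numerical and
design choices made where the domain admits more than one convention, the
parameters of the synthetic-data generator, and the package's known
limitations.

## 1. Domain model

The unit of observation is the **smart pump record (SPR)**: one timestamped
pump event with patient, infusion, drug, dose, dose unit, pump mode, and —
when applicable — an alert type or a nurse response. Four event types exist:
`infusion_start`, `infusion_stop`, `alert`, `response`. Records carry an
`infusion_id` (one physical infusion; it may be started several times, e.g.
after a bag change or pause) and a `module_id` (the pump channel). Where the
two disagree about grouping, **`infusion_id` is authoritative**; `module_id`
is carried through as descriptive metadata only.

A **drug library entry** holds up to four limits per drug and dose unit:
`hard_min ≤ soft_min < soft_max ≤ hard_max`, any of which may be absent.
Infusions programmed in **basic mode** bypass the library entirely and can
never alert; **DERS mode** infusions are checked on every programming.

### Limit semantics

All limit comparisons are **strict**:

* `dose > hard_max` → hard-maximum alert
* `dose > soft_max` → soft-maximum alert
* `dose < hard_min` → hard-minimum alert
* `dose < soft_min` → soft-minimum alert

and at most one alert fires per programming, under the severity precedence
**hard max → soft max → hard min → soft min**. A consequence worth making
explicit: a dose exactly *at* a hard maximum passes the hard check (strict
inequality) but still fires the soft-maximum alert if it exceeds the soft
maximum. This falls directly out of strictness plus precedence and is
asserted by boundary tests rather than special-cased.

Soft alerts admit three responses — `override` (infuse as programmed),
`cancel`, `reprogram` — while hard alerts **force cancellation**; the engine
raises if an override of a hard alert is even attempted. A reprogrammed dose
is re-checked and may itself alert, so one programming attempt can chain
several alerts.

### Percent variance

The variance of a violating dose is reported as
`percent_variance = dose / limit × 100`, so a dose at 29× a hard maximum is a
2900 % variance. Some reporting traditions prefer the *excess* over the limit
(`variance − 100`, i.e. 2800 % for the same dose); the package standardises on
the ratio convention and exposes `excess_over_limit` separately so either can
be quoted.

## 2. Measures

* **Alert frequency** is computed under both denominators in use in the
  field: *alerts per infusion start* (can exceed 100 %: one start may chain
  alerts) and *unique infusions with ≥ 1 alert / unique infusions* (bounded by
  100 %). Unique infusions ≤ starts, since restarts reuse the infusion id.
* **DERS compliance** = starts in DERS mode / all starts.
* **Response distribution** = override / cancel / reprogram shares among
  resolved alerts, reported per year, per drug, and pooled.
* **Alert salience** = (cancelled + reprogrammed) / resolved alerts
  = 1 − override fraction. Salience is counted **at the alert level**, not
  the infusion level: an infusion whose first alert is overridden and second
  cancelled contributes 0.5, not 1. The identity with the override complement
  is enforced by a property test.
* **Averaging conventions.** Multi-year *percentages of starts* (alerting
  rate, DERS compliance) are summarised as the **unweighted mean of yearly
  percentages**; *response percentages* are summarised as **pooled ratios**
  over all alerts. Both conventions appear in published unit reports and they
  do not commute, so the package implements each where the field uses it and
  names the all-years row accordingly.
* **Threshold-violation table**: alerts cross-tabulated by limit type × year
  and by limit type × response, with `verify_conservation` asserting that the
  type margin, the year margin and the response margin (plus unresolved
  alerts) all equal the total alert count, and that hard rows contain no
  overrides or reprograms.
* **Burden tables** slice alerts by shift, day of week, weekend/weekday,
  month, and medication (alerts per 100 starts, override rate, salience,
  multi-alert share). The default shift scheme is day 07–15, evening 15–23,
  night 23–07; any labelled partition of the 24-hour clock can be supplied.
* **Trend across years** uses the Cochran–Armitage test for trend in
  proportions, implemented as the standard score test with equally spaced
  scores (chi-square, 1 df). It was validated against R's `prop.trend.test`
  (agreement to full printed precision on reference inputs) and against a
  permutation null (agreement within 0.02 in p at moderate n).

Alert–response pairing is **FIFO within infusion**: each response resolves
the oldest unresolved alert on the same infusion. Responses without a
matching alert are logged and dropped; unresolved alerts are counted
explicitly and enter the conservation identity.

## 3. Synthetic-data generator

The generator emulates the event stream of a single level-IV NICU so that the
analysis pipeline can be exercised, calibrated and property-tested without
protected health data. It is a mechanism model, not a fit to any particular
dataset.

Structure: admissions arrive uniformly over each year (default 725/year for 3
years starting 2014); length of stay is lognormal with mean 23 days (σ = 0.8
on the log scale); weights are lognormal around 2.6 kg. Each patient-day
draws continuous-infusion orders from a nine-drug mix (opioids/sedatives:
fentanyl, morphine, midazolam; titratable drips: insulin, vasopressin,
dopamine; nutrition/fluids: TPN, lipids, dextrose fluid — the latter three
weighted toward evening shift, when bags are hung). Six of nine drugs carry
hard maxima. Summed daily intensity ≈ 5.4 infusions/patient-day.

Dose-generation and error model, per programming:

* baseline multiplicative lognormal noise around the intended dose
  (`error_sd` per drug, 0.05–0.20);
* **decimal slips**: with probability `p_decimal_10x` (default 0.002) the dose
  is entered at 10× — the classic keying error hard limits exist to catch;
* **priming workarounds**: with probability `p_priming` (default 0.004) a
  line is primed at 2–4× the intended rate for 15–30 minutes, overriding the
  resulting soft alert, then reprogrammed — alerts that are "correct" from
  the pump's view and noise from the nurse's;
* **intended high doses**: probability `p_intended_above_soft` (0.012) of a
  clinically intended dose above the soft max, which re-alerts on every
  restart of that infusion (persistent overriding);
* **dose escalation**: probability `p_escalation` (0.01) that a patient enters
  a late-stay titration episode with 10–25 % step increases, producing the
  heavy multi-alert tail in which a small share of infusions accounts for a
  large share of alerts.

Soft-alert responses are multinomial with default probabilities
(override, cancel, reprogram) = (0.74, 0.23, 0.03); hard alerts always
cancel. A share `p_basic_mode` (0.13) of infusions runs in basic mode.
Restarts per infusion are Poisson-distributed extras (mean 0.4). An optional
`dropout_window` deletes all records in a date interval, emulating an
extraction gap. All randomness flows from a single `numpy` generator seeded
from the config, and same-seed runs are byte-identical on disk.

Every alert in the generated log is produced by calling the same
`check_program` engine used for analysis — the generator cannot emit an alert
the rules would not have raised, and tests replay every generated alert
through the engine to confirm it.

These defaults are the package's **reference study conditions**; under them
the share of starts raising an alert falls in the 2–6 % band typical of
intensive-care drug-library reports, DERS compliance sits near 87 %, and the
response mix matches the configured multinomial. They were fixed from the
mechanism description above and were not adjusted against test outcomes.

### What the generator does *not* model

Bolus/intermittent dosing, loading doses, pump hardware faults, alarm types
other than drug-library limit alerts (occlusion, air-in-line), inter-drug
interactions, clinician identity, order-entry context, or any learning/drift
in nurse behaviour unless explicitly configured (`override_drift_per_year`).
Dose limits are per-drug and unit-static, not weight-band- or
indication-specific.

## 4. Testing approach

Expected values in tests were computed **before** running the code, from
independent sources: hand counts on small engineered logs, a brute-force
classifier and FIFO pairer written without pandas in `tests/naive.py`, a
permutation null for the trend test, and analytic binomial/multinomial
confidence intervals (99 %) for parameter recovery. Property tests
(hypothesis plus seeded sweeps) check conservation identities, engine
monotonicity, salience complements, forced cancellation of hard alerts, and
byte-level determinism. Test problem sizes (3–60 admissions/year, single
years) are scaled down from the defaults purely for runtime; the measures are
size-free counts and ratios, so the scale does not change what is being
verified.

## 5. Limitations

* The generator is a plausibility model; absolute alert counts from it should
  never be quoted as empirical findings — only pipeline behaviour on it.
* FIFO pairing is a convention; real pump logs sometimes carry explicit
  alert–response linkage that, when present, should be preferred upstream.
* The trend test assumes independent programmings; repeated alerts on one
  infusion violate independence, so paper-scale p-values should be read as
  descriptive strength-of-trend, not literal error rates.
* Salience treats cancel and reprogram as equally "effective" responses; it
  does not measure clinical appropriateness of the override decision.
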