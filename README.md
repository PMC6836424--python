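# pumpwatch

Analytics for smart infusion pump event logs in neonatal intensive care.

Smart pumps check every nurse-programmed infusion against a unit-specific
drug library before infusing: doses outside *soft* limits raise overridable
alerts, doses outside *hard* limits force cancellation. This dose error
reduction software (DERS) prevents dangerous overdoses — but it is also a new
source of alerts in an already alarm-dense ICU, and alerts that are almost
always overridden train clinicians to ignore them. Quantifying that tradeoff
requires turning raw pump event streams into a standard suite of
medication-safety surveillance measures.

`pumpwatch` provides that pipeline for safety analysts and clinical
informaticists:

* **`pumpwatch.model`** — domain types for smart-pump records (SPRs), drug
  libraries, infusions and alerts, with lossless CSV readers/writers and
  invariant validation (e.g. a basic-mode infusion can never alert, infusion
  starts ≥ unique infusions).
* **`pumpwatch.engine`** — the DERS rule logic: strict limit classification
  with severity precedence (hard max → soft max → hard min → soft min),
  allowed responses per alert type (hard limits force cancel), reprogram
  re-checking that can chain alerts, and percent variance
  `dose / limit × 100` (a dose of 29× the hard maximum is a 2900% variance).
* **`pumpwatch.metrics`** — the measure suite: alert frequency under both
  denominators (alerts per infusion start; unique infusions with ≥ 1 alert),
  DERS compliance, the override/cancel/reprogram response distribution,
  **alert salience** = (cancelled + reprogrammed) / all alerts
  (= 1 − override fraction, a proxy for alert effectiveness), alert burden by
  shift/day/weekend/month and by medication, the alerts-per-infusion
  histogram, the threshold-violation table with conservation identities, and
  a Cochran–Armitage chi-square test of trend across years (matches R's
  `prop.trend.test`).
* **`pumpwatch.simulate`** — a seeded generator of NICU-like SPR logs
  (admission census, length of stay, a continuous-infusion drug mix,
  programming-noise/decimal-slip/priming-workaround error models, patient-level
  dose-escalation clustering, multinomial nurse responses), so the entire
  pipeline is testable without access to hospital data. Every generated alert
  is produced by the rule engine itself.
* **`pumpwatch.cli`** — `pumpwatch simulate | analyze | report`.

## Worked example

Simulate one year of a 60-admission unit and compute the measure suite:

```python
import dataclasses
from pumpwatch import compute_report
from pumpwatch.simulate import GeneratorConfig, generate_log

cfg = dataclasses.replace(GeneratorConfig(), n_years=1, admissions_per_year=60, seed=1)
records, truth = generate_log(cfg)          # 20,588 events
report = compute_report(records)
```

With seed 1 this prints:

```
starts=9810 unique=7084 alerts=484 pct_starts_with_alerts=4.93
DERS compliance: 86.7%
responses: override 73.1% cancel 23.6% reprogram 3.3%
salience: 0.269
            2014  total  cancel  override  reprogram
alert_type
soft_min      60     60      13        42          5
hard_min       0      0       0         0          0
soft_max     417    417      94       312         11
hard_max       7      7       7         0          0
total        484    484     114       354         16
```

Reading it: 4.9% of the 9,810 infusion starts raised a library alert; 87% of
starts used DERS. Nearly three of four alerts were overridden, so overall
salience is 0.27 — most alerts changed nothing. All 7 hard-maximum violations
were cancelled by the pump (overriding a hard stop is impossible), and the
threshold table's margins are verified to conserve the total alert count
across type, year and response. The same report also shows the
alerts-per-infusion histogram (85.7% of alerting infusions alerted once) and
an evening-heavy shift distribution (45% of alerts), driven by nutrition and
fluid bags hung on evening shift.

The same pipeline from the shell:

```bash
pumpwatch simulate --config config.yaml --out run/ --seed 1
pumpwatch analyze --log run/spr_log.csv --library run/drug_library.csv --out analysis/
pumpwatch report --analysis analysis/ --format csv
```

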