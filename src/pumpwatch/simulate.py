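"""Seeded generator of NICU-like smart-pump event logs.

Real smart-pump exports from a hospital cannot be redistributed, so this
module synthesises logs with the statistical structure such data exhibit,
letting every pipeline stage be exercised end to end:

* a census of admissions per year with log-normal lengths of stay and
  constant per-patient weights;
* a medication mix of continuous NICU infusions (opioids, sedatives,
  vasoactives, insulin, parenteral nutrition and fluids), each with its own
  library limits, daily infusion intensity and programming-noise level;
* roughly 87% of infusions programmed through DERS and the rest in basic
  mode, which bypasses limit checking;
* a dose-error model: multiplicative log-normal programming noise, rare 10x
  decimal-point slips, priming workarounds (rate programmed at 2–4x the
  intended dose for 15–30 minutes to prime tubing quickly), and occasional
  clinically intended above-range doses that re-alert on every restart;
* a clustered-escalation scenario in which a patient's sedative/analgesic is
  repeatedly escalated (10–25% per step), producing the heavy tail of
  multi-alert infusions that concentrates alert burden on a few patients;
* a multinomial nurse-response model over the responses each alert type
  permits (soft alerts default to 74% override / 23% cancel / 3% reprogram;
  hard alerts are always cancelled), with optional drift in override odds
  over time;
* evening-weighted hang times for TPN, lipids and fluids, and an optional
  transmission-dropout window that removes records wholesale.

Every alert in a generated log is produced by running the programmed dose
through :func:`pumpwatch.engine.check_program`, so generated data can never
contradict the engine. All randomness flows from one seeded generator:
identical seeds give byte-identical logs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterator

import numpy as np
import pandas as pd

from . import engine
from .model import (
    AlertType,
    DoseUnit,
    DrugLibraryEntry,
    EventType,
    Mode,
    ResponseAction,
    SmartPumpRecord,
)

__all__ = [
    "DrugSpec",
    "GeneratorConfig",
    "ConfigError",
    "default_drug_mix",
    "generate_log",
    "scenario_presets",
    "config_library",
]

TRUTH_COLUMNS = (
    "row",
    "infusion_id",
    "patient_id",
    "drug_name",
    "event_type",
    "cause",
    "intended_dose",
    "programmed_dose",
    "priming_duration_min",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class DrugSpec:
    """One medication in the simulated mix.

    ``daily_intensity`` is the expected number of new infusions (bags or
    syringes) per patient-day; ``error_sd`` is the standard deviation of the
    log programming noise — drugs with tight limits and high error_sd are the
    high-alerting medications. ``sedative`` marks escalation-eligible drugs;
    ``evening_weighted`` marks infusions predominantly hung on evening shift.
    """

    entry: DrugLibraryEntry
    daily_intensity: float
    error_sd: float = 0.08
    sedative: bool = False
    evening_weighted: bool = False


def default_drug_mix() -> dict[str, DrugSpec]:
    """Continuous-infusion mix typical of a level IV NICU.

    Limits are in weight-based dosing units for drips and mL/hr for
    nutrition/fluids (rate-governed entries); about 60% of entries carry hard
    maxima, as neonatal libraries commonly do. Summed intensity is ~5.4 new
    infusions per patient-day, dominated by nutrition and fluid bags.
    """

    def entry(name, unit, smin, smax, hmin, hmax):
        return DrugLibraryEntry(name, unit, soft_min=smin, soft_max=smax, hard_min=hmin, hard_max=hmax)

    return {
        "fentanyl": DrugSpec(
            entry("fentanyl", DoseUnit.MCG_KG_HR, 0.5, 4.0, None, 10.0),
            daily_intensity=0.5, error_sd=0.18, sedative=True,
        ),
        "morphine": DrugSpec(
            entry("morphine", DoseUnit.MG_KG_HR, 0.01, 0.04, None, 0.1),
            daily_intensity=0.4, error_sd=0.15, sedative=True,
        ),
        "midazolam": DrugSpec(
            entry("midazolam", DoseUnit.MG_KG_HR, 0.03, 0.12, None, 0.3),
            daily_intensity=0.35, error_sd=0.12, sedative=True,
        ),
        "insulin": DrugSpec(
            entry("insulin", DoseUnit.UNITS_KG_HR, 0.01, 0.1, None, 0.2),
            daily_intensity=0.25, error_sd=0.2,
        ),
        "vasopressin": DrugSpec(
            entry("vasopressin", DoseUnit.UNITS_KG_HR, 0.0005, 0.002, None, 0.004),
            daily_intensity=0.2, error_sd=0.2,
        ),
        "dopamine": DrugSpec(
            entry("dopamine", DoseUnit.MCG_KG_MIN, 2.0, 20.0, None, 25.0),
            daily_intensity=0.3, error_sd=0.08,
        ),
        "TPN": DrugSpec(
            entry("TPN", DoseUnit.ML_HR, 1.0, 25.0, None, None),
            daily_intensity=1.2, error_sd=0.06, evening_weighted=True,
        ),
        "lipids": DrugSpec(
            entry("lipids", DoseUnit.ML_HR, 0.5, 4.0, None, None),
            daily_intensity=1.0, error_sd=0.06, evening_weighted=True,
        ),
        "dextrose_fluid": DrugSpec(
            entry("dextrose_fluid", DoseUnit.ML_HR, 1.0, 30.0, None, None),
            daily_intensity=1.2, error_sd=0.05, evening_weighted=True,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated unit.

    Defaults emulate the published NICU setting: ~725 admissions/year with a
    mean 23-day stay, 13% basic-mode programming, soft-alert responses of
    74% override / 23% cancel / 3% reprogram, and error-model rates tuned so
    that a few percent of infusion starts alert.
    """

    seed: int = 0
    n_years: int = 3
    start_year: int = 2014
    admissions_per_year: int = 725
    los_mean_days: float = 23.0
    los_sigma: float = 0.8
    mean_weight_kg: float = 2.6
    weight_sigma: float = 0.45
    p_basic_mode: float = 0.13
    p_decimal_10x: float = 0.002
    p_priming: float = 0.004
    p_intended_above_soft: float = 0.012
    p_escalation: float = 0.01
    escalation_step_low: float = 1.10
    escalation_step_high: float = 1.25
    escalation_mean_steps: float = 8.0
    soft_response_probs: tuple[float, float, float] = (0.74, 0.23, 0.03)
    override_drift_per_year: float = 0.0
    restart_mean_extra: float = 0.4
    max_alerts_per_infusion: int = 34
    dropout_window: tuple[str, str] | None = None
    drugs: dict[str, DrugSpec] = field(default_factory=default_drug_mix)

    def __post_init__(self) -> None:
        for name in ("p_basic_mode", "p_decimal_10x", "p_priming",
                     "p_intended_above_soft", "p_escalation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        probs = self.soft_response_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("soft_response_probs must be 3 non-negative values summing to 1")
        if not self.drugs:
            raise ConfigError("drug mix is empty")
        for name, spec in self.drugs.items():
            if spec.entry is None:
                raise ConfigError(f"drug {name!r} in mix has no library entry")
            if name != spec.entry.drug_name:
                raise ConfigError(f"drug mix key {name!r} != entry name {spec.entry.drug_name!r}")
        if self.n_years < 1 or self.admissions_per_year < 1:
            raise ConfigError("need at least one year and one admission")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drugs"] = {
            name: {
                "dose_unit": spec.entry.dose_unit.value,
                "soft_min": spec.entry.soft_min,
                "soft_max": spec.entry.soft_max,
                "hard_min": spec.entry.hard_min,
                "hard_max": spec.entry.hard_max,
                "daily_intensity": spec.daily_intensity,
                "error_sd": spec.error_sd,
                "sedative": spec.sedative,
                "evening_weighted": spec.evening_weighted,
            }
            for name, spec in self.drugs.items()
        }
        if d["dropout_window"] is not None:
            d["dropout_window"] = list(d["dropout_window"])
        d["soft_response_probs"] = list(d["soft_response_probs"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        drugs_raw = data.pop("drugs", None)
        if drugs_raw is not None:
            drugs = {}
            for name, spec in drugs_raw.items():
                try:
                    entry = DrugLibraryEntry(
                        drug_name=name,
                        dose_unit=DoseUnit(spec["dose_unit"]),
                        soft_min=spec.get("soft_min"),
                        soft_max=spec.get("soft_max"),
                        hard_min=spec.get("hard_min"),
                        hard_max=spec.get("hard_max"),
                    )
                except KeyError as exc:
                    raise ConfigError(f"drug {name!r}: missing field {exc}") from exc
                drugs[name] = DrugSpec(
                    entry=entry,
                    daily_intensity=float(spec["daily_intensity"]),
                    error_sd=float(spec.get("error_sd", 0.08)),
                    sedative=bool(spec.get("sedative", False)),
                    evening_weighted=bool(spec.get("evening_weighted", False)),
                )
            data["drugs"] = drugs
        if data.get("soft_response_probs") is not None:
            data["soft_response_probs"] = tuple(data["soft_response_probs"])
        if data.get("dropout_window") is not None:
            data["dropout_window"] = tuple(data["dropout_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def config_library(config: GeneratorConfig) -> dict[str, DrugLibraryEntry]:
    """The drug library implied by a config's medication mix."""
    return {name: spec.entry for name, spec in config.drugs.items()}


def scenario_presets() -> dict[str, GeneratorConfig]:
    """Named study scenarios.

    * ``baseline`` — published-setting rates;
    * ``clustered`` — escalation scenario on, concentrating repeat alerts on
      few patients/infusions;
    * ``priming`` — elevated rate of 2–4x priming workarounds;
    * ``dropout2015`` — wireless-transmission loss from August through
      December of the second study year.
    """
    baseline = GeneratorConfig()
    return {
        "baseline": baseline,
        "clustered": replace(baseline, p_escalation=0.08),
        "priming": replace(baseline, p_priming=0.03),
        "dropout2015": replace(baseline, dropout_window=("2015-08-01", "2016-01-01")),
    }


# ---------------------------------------------------------------------------
# Generation internals
# ---------------------------------------------------------------------------

_CAUSES = ("baseline", "decimal_slip", "priming", "escalation", "high_dose_intent")


class _LogBuilder:
    """Accumulates (record, annotation) pairs during a simulation run."""

    def __init__(self) -> None:
        self.rows: list[tuple[SmartPumpRecord, dict | None]] = []

    def emit(
        self,
        ts: datetime,
        *,
        pump: str,
        module: str,
        infusion_id: str,
        patient_id: str,
        drug: str,
        dose: float,
        unit: DoseUnit,
        rate: float,
        weight: float,
        mode: Mode,
        event_type: EventType,
        alert_type: AlertType = AlertType.NONE,
        response: ResponseAction = ResponseAction.NONE,
        ann: dict | None = None,
    ) -> None:
        rec = SmartPumpRecord(
            timestamp=ts.replace(microsecond=0),
            pump_unit_id=pump,
            module_id=module,
            infusion_id=infusion_id,
            patient_id=patient_id,
            drug_name=drug,
            dose_value=dose,
            dose_unit=unit,
            rate_ml_hr=rate,
            weight_kg=weight,
            mode=mode,
            event_type=event_type,
            alert_type=alert_type,
            response_action=response,
        )
        self.rows.append((rec, ann))


def _sample_soft_response(
    rng: np.random.Generator, config: GeneratorConfig, years_elapsed: float
) -> ResponseAction:
    p_o, p_c, p_r = config.soft_response_probs
    if config.override_drift_per_year != 0.0 and 0.0 < p_o < 1.0:
        logit = np.log(p_o / (1 - p_o)) + config.override_drift_per_year * years_elapsed
        p_o_t = 1.0 / (1.0 + np.exp(-logit))
        rest = 1.0 - p_o_t
        denom = p_c + p_r
        p_c_t = rest * (p_c / denom) if denom > 0 else rest
        p_r_t = rest - p_c_t
        probs = np.array([p_o_t, p_c_t, p_r_t])
    else:
        probs = np.array([p_o, p_c, p_r])
    idx = rng.choice(3, p=probs / probs.sum())
    return (ResponseAction.OVERRIDE, ResponseAction.CANCEL, ResponseAction.REPROGRAM)[int(idx)]


def _intended_band(entry: DrugLibraryEntry) -> tuple[float, float]:
    if entry.soft_min is not None and entry.soft_max is not None:
        return entry.soft_min, entry.soft_max
    if entry.hard_max is not None:
        lo = entry.hard_min if entry.hard_min is not None else 0.1 * entry.hard_max
        return lo, 0.8 * entry.hard_max
    return 1.0, 10.0


class _Simulator:
    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.builder = _LogBuilder()
        self.inf_counter = 0
        self.horizon = datetime(config.start_year + config.n_years, 1, 1) - timedelta(minutes=5)
        self.t0 = datetime(config.start_year, 1, 1)

    # -- sampling helpers --------------------------------------------------

    def _lognormal_mean(self, mean: float, sigma: float) -> float:
        mu = np.log(mean) - sigma**2 / 2.0
        return float(self.rng.lognormal(mu, sigma))

    def _start_time(self, admit: datetime, discharge: datetime, evening: bool) -> datetime:
        span = (discharge - admit).total_seconds()
        t = admit + timedelta(seconds=float(self.rng.uniform(0, max(span, 60.0))))
        if evening and self.rng.random() < 0.6:
            # new nutrition/fluid bags are predominantly hung on evening shift
            hour = float(self.rng.uniform(15, 23))
            t = t.replace(hour=int(hour), minute=int((hour % 1) * 60))
            t = min(max(t, admit), discharge)
        return min(t, self.horizon)

    def _programmed_dose(self, intended: float, spec: DrugSpec) -> tuple[float, str, float | None]:
        """Apply the dose-error model to an intended dose."""
        u = self.rng.random()
        if u < self.cfg.p_decimal_10x:
            return intended * 10.0, "decimal_slip", None
        if u < self.cfg.p_decimal_10x + self.cfg.p_priming:
            factor = float(self.rng.uniform(2.0, 4.0))
            duration = float(self.rng.uniform(15.0, 30.0))
            return intended * factor, "priming", duration
        noise = float(self.rng.lognormal(0.0, spec.error_sd))
        return intended * noise, "baseline", None

    # -- programming episode -----------------------------------------------

    def _program(
        self,
        t: datetime,
        ctx: dict,
        intended: float,
        spec: DrugSpec,
        alerts_so_far: int,
        forced_dose: float | None = None,
        forced_cause: str | None = None,
    ) -> tuple[datetime, float, int]:
        """Run one programming episode: attempts, alerts, responses, a start.

        Returns (time cursor after the start, accepted dose, alerts raised).
        Always terminates in a start: clinically the medication is needed, so
        after repeated cancels the nurse programs a dose within limits.
        """
        cfg, rng, entry = self.cfg, self.rng, spec.entry
        lo, hi = _intended_band(entry)
        safe_dose = (lo + hi) / 2.0
        if forced_dose is not None:
            dose, cause, priming_min = forced_dose, forced_cause or "baseline", None
        else:
            dose, cause, priming_min = self._programmed_dose(intended, spec)
        n_alerts = 0
        attempts = 0
        while True:
            attempts += 1
            if alerts_so_far + n_alerts >= cfg.max_alerts_per_infusion:
                dose, cause, priming_min = safe_dose, "baseline", None
            result = engine.check_program(dose, entry, mode=Mode.DERS)
            if not result.alerted:
                self.builder.emit(
                    t, event_type=EventType.INFUSION_START, dose=dose,
                    alert_type=AlertType.NONE,
                    ann={"cause": cause, "intended_dose": intended, "programmed_dose": dose,
                         "priming_duration_min": priming_min},
                    **ctx,
                )
                return t, dose, n_alerts
            n_alerts += 1
            self.builder.emit(
                t, event_type=EventType.ALERT, dose=dose, alert_type=result.alert_type,
                ann={"cause": cause, "intended_dose": intended, "programmed_dose": dose,
                     "priming_duration_min": priming_min},
                **ctx,
            )
            t_resp = t + timedelta(seconds=float(rng.uniform(10, 90)))
            years_elapsed = (t - self.t0).total_seconds() / (365.25 * 86400)
            if result.alert_type.is_hard:
                action = ResponseAction.CANCEL
            else:
                action = _sample_soft_response(rng, cfg, years_elapsed)
            self.builder.emit(
                t_resp, event_type=EventType.RESPONSE, dose=dose, response=action, **ctx
            )
            t = t_resp + timedelta(seconds=float(rng.uniform(20, 120)))
            if action is ResponseAction.OVERRIDE:
                self.builder.emit(
                    t, event_type=EventType.INFUSION_START, dose=dose,
                    ann={"cause": cause, "intended_dose": intended, "programmed_dose": dose,
                         "priming_duration_min": priming_min},
                    **ctx,
                )
                # an overridden priming workaround runs 15-30 min, then the
                # pump is stopped and reprogrammed at the intended dose
                if cause == "priming" and priming_min is not None:
                    t_stop = t + timedelta(minutes=priming_min)
                    self.builder.emit(t_stop, event_type=EventType.STOP, dose=dose, **ctx)
                    t2 = t_stop + timedelta(seconds=float(rng.uniform(30, 120)))
                    t2, accepted, extra = self._program(
                        t2, ctx, intended, spec, alerts_so_far + n_alerts,
                        forced_dose=float(np.clip(intended, lo, hi)), forced_cause="baseline",
                    )
                    return t2, accepted, n_alerts + extra
                return t, dose, n_alerts
            if action is ResponseAction.CANCEL:
                if attempts >= 3 or cause in ("decimal_slip", "priming"):
                    dose, cause, priming_min = float(np.clip(intended, lo, hi)), "baseline", None
                else:
                    noise = float(rng.lognormal(0.0, spec.error_sd / 2.0))
                    dose, cause, priming_min = intended * noise, cause, None
                continue
            # reprogram: the corrected dose goes back through the limit check
            if attempts >= 3:
                dose = safe_dose
            else:
                noise = float(rng.lognormal(0.0, spec.error_sd / 2.0))
                dose = float(np.clip(intended, lo, hi)) * noise
            cause, priming_min = "baseline", None

    # -- whole infusions ----------------------------------------------------

    def _simulate_infusion(
        self,
        drug: str,
        spec: DrugSpec,
        patient_id: str,
        weight: float,
        admit: datetime,
        discharge: datetime,
    ) -> None:
        cfg, rng = self.cfg, self.rng
        self.inf_counter += 1
        infusion_id = f"INF{self.inf_counter:08d}"
        entry = spec.entry
        rate = float(rng.uniform(0.2, 20.0))
        ctx = {
            "pump": f"PCU{int(rng.integers(0, 30)):03d}",
            "module": f"M{int(rng.integers(1, 5))}",
            "infusion_id": infusion_id,
            "patient_id": patient_id,
            "drug": drug,
            "unit": entry.dose_unit,
            "rate": rate,
            "weight": weight,
        }
        t = self._start_time(admit, discharge, spec.evening_weighted)
        mode = Mode.BASIC if rng.random() < cfg.p_basic_mode else Mode.DERS

        lo, hi = _intended_band(entry)
        intended = float(rng.uniform(lo, hi))
        persistent_high = False
        if (
            mode is Mode.DERS
            and entry.soft_max is not None
            and rng.random() < cfg.p_intended_above_soft
        ):
            # clinically required above-range dose: alerts on every program
            top = entry.hard_max * 0.95 if entry.hard_max is not None else entry.soft_max * 1.6
            intended = float(
                np.clip(entry.soft_max * rng.uniform(1.05, 1.5), entry.soft_max * 1.01, top)
            )
            persistent_high = True

        n_episodes = 1 + int(rng.poisson(cfg.restart_mean_extra))
        accepted: float | None = None
        alerts_so_far = 0
        for ep in range(n_episodes):
            if t >= min(discharge, self.horizon):
                break
            if mode is Mode.BASIC:
                self.builder.emit(
                    t, event_type=EventType.INFUSION_START, dose=intended,
                    mode=mode,
                    ann={"cause": "baseline", "intended_dose": intended,
                         "programmed_dose": intended, "priming_duration_min": None},
                    **ctx,
                )
                accepted = intended
            elif ep == 0 or persistent_high or accepted is None:
                cause = "high_dose_intent" if persistent_high else None
                forced = intended if persistent_high else None
                t, accepted, n_new = self._program(
                    t, dict(ctx, mode=mode), intended, spec, alerts_so_far,
                    forced_dose=forced, forced_cause=cause,
                )
                alerts_so_far += n_new
            else:
                # restart of an already-accepted program: no re-check alert
                self.builder.emit(
                    t, event_type=EventType.INFUSION_START, dose=accepted, mode=mode,
                    ann={"cause": "baseline", "intended_dose": intended,
                         "programmed_dose": accepted, "priming_duration_min": None},
                    **ctx,
                )
            run_hours = min(
                self._lognormal_mean(10.0, 0.8),
                max((min(discharge, self.horizon) - t).total_seconds() / 3600.0, 0.25),
            )
            t = t + timedelta(hours=max(run_hours, 0.25))
            t = min(t, self.horizon)
            self.builder.emit(
                t, event_type=EventType.STOP, dose=accepted if accepted is not None else intended,
                mode=mode, **ctx,
            )
            t = t + timedelta(minutes=float(rng.uniform(1, 30)))

    def _simulate_escalation(
        self,
        drug: str,
        spec: DrugSpec,
        patient_id: str,
        weight: float,
        admit: datetime,
        discharge: datetime,
    ) -> None:
        """One sedative/analgesic infusion whose dose is escalated in steps.

        Each 10–25% step re-programs the pump; once past the soft maximum
        every step alerts, and steps beyond the hard maximum are forcibly
        cancelled and re-entered just below it. This concentrates many alerts
        on one infusion of one patient — the clustered-burden phenomenon.
        """
        cfg, rng = self.cfg, self.rng
        self.inf_counter += 1
        infusion_id = f"INF{self.inf_counter:08d}"
        entry = spec.entry
        ctx = {
            "pump": f"PCU{int(rng.integers(0, 30)):03d}",
            "module": f"M{int(rng.integers(1, 5))}",
            "infusion_id": infusion_id,
            "patient_id": patient_id,
            "drug": drug,
            "unit": entry.dose_unit,
            "rate": float(rng.uniform(0.2, 20.0)),
            "weight": weight,
            "mode": Mode.DERS,
        }
        # escalation typically occurs late in the stay
        span = (discharge - admit).total_seconds()
        t = admit + timedelta(seconds=0.7 * span)
        t = min(t, self.horizon - timedelta(hours=1))
        if t <= admit:
            t = admit
        lo, hi = _intended_band(entry)
        dose = (entry.soft_max if entry.soft_max is not None else hi) * 0.9
        n_steps = 4 + int(rng.poisson(cfg.escalation_mean_steps))
        alerts_so_far = 0
        for step in range(n_steps):
            if t >= min(discharge, self.horizon) or alerts_so_far >= cfg.max_alerts_per_infusion:
                break
            if entry.hard_max is not None and dose > entry.hard_max:
                dose = entry.hard_max * 0.98
            t, _, n_new = self._program(
                t, ctx, dose, spec, alerts_so_far, forced_dose=dose, forced_cause="escalation"
            )
            alerts_so_far += n_new
            run_hours = float(rng.uniform(0.5, 4.0))
            t = min(t + timedelta(hours=run_hours), self.horizon)
            self.builder.emit(t, event_type=EventType.STOP, dose=dose, **ctx)
            t = t + timedelta(minutes=float(rng.uniform(2, 20)))
            dose *= float(rng.uniform(cfg.escalation_step_low, cfg.escalation_step_high))

    # -- run ----------------------------------------------------------------

    def run(self) -> tuple[list[SmartPumpRecord], pd.DataFrame]:
        cfg, rng = self.cfg, self.rng
        drug_names = list(cfg.drugs)
        sedatives = [n for n in drug_names if cfg.drugs[n].sedative]
        for y in range(cfg.n_years):
            year_start = datetime(cfg.start_year + y, 1, 1)
            year_seconds = (datetime(cfg.start_year + y + 1, 1, 1) - year_start).total_seconds()
            for a in range(cfg.admissions_per_year):
                patient_id = f"P{cfg.start_year + y}{a:05d}"
                weight = float(
                    np.clip(
                        rng.lognormal(np.log(cfg.mean_weight_kg) - cfg.weight_sigma**2 / 2,
                                      cfg.weight_sigma),
                        0.4, 8.0,
                    )
                )
                admit = year_start + timedelta(seconds=float(rng.uniform(0, year_seconds)))
                los_days = max(self._lognormal_mean(cfg.los_mean_days, cfg.los_sigma), 0.5)
                discharge = min(admit + timedelta(days=los_days), self.horizon)
                for drug in drug_names:
                    spec = cfg.drugs[drug]
                    n_inf = int(rng.poisson(spec.daily_intensity * los_days))
                    for _ in range(n_inf):
                        self._simulate_infusion(drug, spec, patient_id, weight, admit, discharge)
                if sedatives and rng.random() < cfg.p_escalation:
                    drug = sedatives[int(rng.integers(0, len(sedatives)))]
                    self._simulate_escalation(
                        drug, cfg.drugs[drug], patient_id, weight, admit, discharge
                    )
        return self._finalise()

    def _finalise(self) -> tuple[list[SmartPumpRecord], pd.DataFrame]:
        rows = self.builder.rows
        order = sorted(range(len(rows)), key=lambda i: (rows[i][0].timestamp, i))
        rows = [rows[i] for i in order]
        if self.cfg.dropout_window is not None:
            w0 = datetime.fromisoformat(self.cfg.dropout_window[0])
            w1 = datetime.fromisoformat(self.cfg.dropout_window[1])
            rows = [(r, a) for r, a in rows if not (w0 <= r.timestamp < w1)]
        records = [r for r, _ in rows]
        truth_rows = []
        for i, (r, ann) in enumerate(rows):
            if ann is not None:
                truth_rows.append(
                    {
                        "row": i,
                        "infusion_id": r.infusion_id,
                        "patient_id": r.patient_id,
                        "drug_name": r.drug_name,
                        "event_type": r.event_type.value,
                        "cause": ann["cause"],
                        "intended_dose": ann["intended_dose"],
                        "programmed_dose": ann["programmed_dose"],
                        "priming_duration_min": ann["priming_duration_min"],
                    }
                )
        truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
        return records, truth


def generate_log(config: GeneratorConfig) -> tuple[list[SmartPumpRecord], pd.DataFrame]:
    """Generate an ordered SPR log and its ground-truth annotation table.

    The log is globally sorted by timestamp (stable) and satisfies all domain
    invariants; every alert was produced by the limit-checking engine on the
    sampled programmed dose. The truth table has one row per start and alert
    event (keyed by 0-based row index into the log) recording the latent cause
    of the programming — baseline noise, decimal slip, priming workaround,
    dose escalation, or an intended above-range dose.
    """
    return _Simulator(config).run()
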