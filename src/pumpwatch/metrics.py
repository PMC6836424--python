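"""Alert-burden, salience, and threshold-violation measures for SPR logs.

Given an event log (list of :class:`~pumpwatch.model.SmartPumpRecord` or a
DataFrame in the canonical dialect), this module computes the full measure
suite of a medication-safety surveillance analysis:

* infusion frequency (starts and unique infusions) and alert frequency under
  both denominators — alerts per infusion start, and unique infusions with at
  least one alert per unique infusion;
* drug-library compliance (share of starts programmed through DERS);
* the override / cancel / reprogram response distribution;
* alert salience — (cancelled + reprogrammed alerts) / all alerts — a proxy
  for how often an alert triggers corrective action;
* alert burden by nursing shift, day of week, weekday/weekend and month, and
  by medication;
* the threshold-violation table (alert type x year, with per-type response
  counts) whose marginals must satisfy conservation identities;
* the alerts-per-infusion histogram (1 / 2 / 3 / >=4 alerts);
* a Cochran–Armitage chi-square test of trend across ordered years.

Two averaging conventions coexist in the yearly summary and both are
implemented deliberately: percentages *of starts* are averaged as unweighted
means of the yearly percentages, while response percentages are pooled ratios
over all years. :class:`MetricReport` bundles every table and serialises to
CSV or JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    AlertType,
    EventType,
    Mode,
    ResponseAction,
    SmartPumpRecord,
    records_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftScheme",
    "DEFAULT_SHIFT_SCHEME",
    "MetricReport",
    "ConservationError",
    "as_frame",
    "pair_alerts",
    "alert_frequency",
    "ders_compliance",
    "response_distribution",
    "alert_salience",
    "threshold_violation_table",
    "burden_by_time",
    "burden_by_medication",
    "alerts_per_infusion_histogram",
    "chi_square_trend",
    "unweighted_yearly_mean",
    "verify_conservation",
    "compute_report",
]

ALERT_TYPE_ORDER = ["soft_min", "hard_min", "soft_max", "hard_max"]
RESPONSE_ORDER = ["override", "cancel", "reprogram"]


class ConservationError(AssertionError):
    """An alert-count conservation identity failed for a log."""


# ---------------------------------------------------------------------------
# Shift scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftScheme:
    """Labelled local-time intervals partitioning the 24-hour clock.

    ``shifts`` maps a label to a half-open hour interval [start, end); an
    interval with start >= end wraps past midnight. The default is the
    conventional 8-hour nursing pattern: day 07–15, evening 15–23,
    night 23–07.
    """

    shifts: tuple[tuple[str, int, int], ...] = (
        ("day", 7, 15),
        ("evening", 15, 23),
        ("night", 23, 7),
    )

    def __post_init__(self) -> None:
        covered = np.zeros(24, dtype=int)
        for label, start, end in self.shifts:
            if not (0 <= start < 24 and 0 <= end < 24):
                raise ValueError(f"shift {label!r}: hours must be in [0, 24)")
            hours = range(start, end) if start < end else [*range(start, 24), *range(0, end)]
            for h in hours:
                covered[h] += 1
        if not (covered == 1).all():
            raise ValueError("shift intervals must partition the 24-hour clock exactly")

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.shifts]

    def assign(self, hours: np.ndarray | pd.Series) -> pd.Series:
        hours = pd.Series(np.asarray(hours))
        out = pd.Series(pd.NA, index=hours.index, dtype="object")
        for label, start, end in self.shifts:
            mask = (hours >= start) & (hours < end) if start < end else (hours >= start) | (hours < end)
            out[mask] = label
        return out

    @classmethod
    def from_mapping(cls, spec: dict) -> "ShiftScheme":
        return cls(tuple((str(k), int(v[0]), int(v[1])) for k, v in spec.items()))


DEFAULT_SHIFT_SCHEME = ShiftScheme()


# ---------------------------------------------------------------------------
# Log coercion and alert/response pairing
# ---------------------------------------------------------------------------

def as_frame(log: pd.DataFrame | Sequence[SmartPumpRecord]) -> pd.DataFrame:
    """Coerce a log to the canonical DataFrame with a ``year`` column added."""
    frame = log if isinstance(log, pd.DataFrame) else records_to_frame(log)
    frame = frame.reset_index(drop=True)
    ts = pd.to_datetime(frame["timestamp"])
    frame = frame.assign(timestamp=ts, year=ts.dt.year)
    return frame


def pair_alerts(log: pd.DataFrame | Sequence[SmartPumpRecord]) -> pd.DataFrame:
    """Resolve each alert event with the next response event of its infusion.

    Returns one row per alert with columns ``timestamp, year, infusion_id,
    patient_id, drug_name, alert_type, response``; ``response`` is NaN for
    alerts left unresolved at the end of the log (these are excluded from
    response distributions but still counted as alerts). Matching is
    first-in-first-out within an infusion, consistent with a pump that blocks
    on an alert until the clinician acts.
    """
    frame = as_frame(log)
    ar = frame[frame["event_type"].isin([EventType.ALERT.value, EventType.RESPONSE.value])]
    out_rows: list[dict] = []
    n_unresolved = 0
    for infusion_id, grp in ar.groupby("infusion_id", sort=False):
        pending: list[dict] = []
        for row in grp.itertuples(index=False):
            if row.event_type == EventType.ALERT.value:
                pending.append(
                    {
                        "timestamp": row.timestamp,
                        "year": row.year,
                        "infusion_id": infusion_id,
                        "patient_id": row.patient_id,
                        "drug_name": row.drug_name,
                        "alert_type": row.alert_type,
                        "attempted_dose": row.dose_value,
                        "response": None,
                    }
                )
            else:  # response
                for alert in pending:
                    if alert["response"] is None:
                        alert["response"] = row.response_action
                        break
                else:
                    logger.warning(
                        "infusion %s: response with no pending alert ignored in pairing",
                        infusion_id,
                    )
        n_unresolved += sum(1 for a in pending if a["response"] is None)
        out_rows.extend(pending)
    if n_unresolved:
        logger.warning(
            "%d alert(s) unresolved at end of log; excluded from response distributions",
            n_unresolved,
        )
    columns = [
        "timestamp",
        "year",
        "infusion_id",
        "patient_id",
        "drug_name",
        "alert_type",
        "attempted_dose",
        "response",
    ]
    paired = pd.DataFrame(out_rows, columns=columns)
    return paired.sort_values("timestamp", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Frequencies and compliance
# ---------------------------------------------------------------------------

def _yearly_index(years: Sequence[int]) -> list:
    return sorted(set(int(y) for y in years))


def unweighted_yearly_mean(values: pd.Series | Sequence[float]) -> float:
    """All-years average as the unweighted mean of yearly values."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


def alert_frequency(log: pd.DataFrame | Sequence[SmartPumpRecord]) -> pd.DataFrame:
    """Alert frequency per year under both denominators, plus all-years row.

    * ``pct_starts_with_alerts`` — total alerts / total infusion starts x 100
      (may in principle exceed 100%);
    * ``pct_infusions_with_alerts`` — unique infusions with >=1 alert /
      unique infusions x 100 (bounded by 100%).

    A unique infusion is attributed to the calendar year of its first start.
    All-years percentage cells are unweighted means of the yearly
    percentages; count cells are likewise means (so they mirror a
    per-year-average convention).
    """
    frame = as_frame(log)
    starts = frame[frame["event_type"] == EventType.INFUSION_START.value]
    alerts = frame[frame["event_type"] == EventType.ALERT.value]
    years = _yearly_index(frame["year"]) if len(frame) else []

    first_start_year = starts.groupby("infusion_id", sort=False)["year"].first()
    alerting_ids = set(alerts["infusion_id"])

    rows = {}
    for year in years:
        n_starts = int((starts["year"] == year).sum())
        ids = first_start_year[first_start_year == year].index
        n_unique = len(ids)
        n_alerts = int((alerts["year"] == year).sum())
        n_alerting = sum(1 for i in ids if i in alerting_ids)
        rows[year] = {
            "n_infusion_starts": n_starts,
            "n_unique_infusions": n_unique,
            "n_alerts": n_alerts,
            "n_infusions_with_alerts": n_alerting,
            "pct_starts_with_alerts": 100.0 * n_alerts / n_starts if n_starts else np.nan,
            "pct_infusions_with_alerts": 100.0 * n_alerting / n_unique if n_unique else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table.loc["all_years"] = table.mean(axis=0)
    else:
        table = pd.DataFrame(
            columns=[
                "n_infusion_starts",
                "n_unique_infusions",
                "n_alerts",
                "n_infusions_with_alerts",
                "pct_starts_with_alerts",
                "pct_infusions_with_alerts",
            ]
        )
    table.index.name = "year"
    return table


def ders_compliance(log: pd.DataFrame | Sequence[SmartPumpRecord]) -> pd.DataFrame:
    """Share of infusion starts programmed through the drug library (DERS).

    Per year plus an all-years unweighted mean; the two shares sum to 100%
    within each year. ``pct_ders_rounded`` carries the integer-percent
    headline figure.
    """
    frame = as_frame(log)
    starts = frame[frame["event_type"] == EventType.INFUSION_START.value]
    rows = {}
    for year in _yearly_index(starts["year"]) if len(starts) else []:
        sub = starts[starts["year"] == year]
        n = len(sub)
        n_ders = int((sub["mode"] == Mode.DERS.value).sum())
        rows[year] = {
            "n_starts": n,
            "pct_ders": 100.0 * n_ders / n,
            "pct_basic": 100.0 * (n - n_ders) / n,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table.loc["all_years"] = table.mean(axis=0)
    else:
        table = pd.DataFrame(columns=["n_starts", "pct_ders", "pct_basic"])
    table["pct_ders_rounded"] = table["pct_ders"].round(0) if len(table) else pd.Series(dtype=float)
    table.index.name = "year"
    return table


# ---------------------------------------------------------------------------
# Responses and salience
# ---------------------------------------------------------------------------

def response_distribution(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    by: str | None = "year",
    paired: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Override / cancel / reprogram counts and percentages per stratum.

    ``by`` may be ``"year"``, ``"drug_name"`` or ``None`` (pooled only).
    Percentages within a stratum are category count / resolved alerts in that
    stratum. The pooled row uses the all-years totals (a pooled ratio, not a
    mean of yearly percentages). Unresolved alerts are excluded.
    """
    paired = pair_alerts(log) if paired is None else paired
    resolved = paired.dropna(subset=["response"])
    groups: list[tuple[object, pd.DataFrame]] = []
    if by is not None and len(resolved):
        groups = [(k, g) for k, g in resolved.groupby(by, sort=True)]
    groups.append(("pooled", resolved))
    rows = {}
    for key, grp in groups:
        n = len(grp)
        counts = grp["response"].value_counts()
        row: dict[str, float] = {"n_resolved_alerts": n}
        for action in RESPONSE_ORDER:
            c = int(counts.get(action, 0))
            row[f"n_{action}"] = c
            row[f"pct_{action}"] = 100.0 * c / n if n else np.nan
        rows[key] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = by or "stratum"
    return table


def alert_salience(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    by: str | None = None,
    paired: pd.DataFrame | None = None,
) -> pd.DataFrame | float:
    """Alert salience: corrective responses (cancel + reprogram) / all alerts.

    A fraction in [0, 1], identically 1 − override fraction. Low salience
    means most alerts pass without changing the programmed infusion — the
    signature of alert fatigue. ``by=None`` returns the overall scalar;
    ``by="drug_name"`` (or ``"year"``) returns a per-stratum table. Strata
    with no resolved alerts are reported as NaN.
    """
    paired = pair_alerts(log) if paired is None else paired
    resolved = paired.dropna(subset=["response"])

    def _salience(grp: pd.DataFrame) -> float:
        n = len(grp)
        if n == 0:
            return float("nan")
        corrective = grp["response"].isin([ResponseAction.CANCEL.value, ResponseAction.REPROGRAM.value]).sum()
        return float(corrective) / n

    if by is None:
        return _salience(resolved)
    rows = {key: {"n_resolved_alerts": len(grp), "salience": _salience(grp)}
            for key, grp in resolved.groupby(by, sort=True)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = by
    return table


# ---------------------------------------------------------------------------
# Threshold-violation table and conservation
# ---------------------------------------------------------------------------

def threshold_violation_table(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    paired: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Violation counts by alert type x year, with per-type response counts.

    Rows are the four threshold types plus a ``total`` row; columns are each
    calendar year, ``total``, then ``cancel`` / ``override`` / ``reprogram``
    counts. Response columns count resolved alerts only, so the three response
    totals sum to the number of resolved alerts (equal to ``total`` when the
    log is not truncated mid-alert).
    """
    paired = pair_alerts(log) if paired is None else paired
    years = _yearly_index(paired["year"]) if len(paired) else []
    table = pd.DataFrame(
        0, index=ALERT_TYPE_ORDER + ["total"], columns=[*years, "total", *["cancel", "override", "reprogram"]]
    )
    if len(paired):
        by_year = paired.pivot_table(index="alert_type", columns="year", aggfunc="size", fill_value=0)
        for at in ALERT_TYPE_ORDER:
            for year in years:
                if at in by_year.index and year in by_year.columns:
                    table.loc[at, year] = int(by_year.loc[at, year])
        resolved = paired.dropna(subset=["response"])
        by_resp = resolved.pivot_table(index="alert_type", columns="response", aggfunc="size", fill_value=0)
        for at in ALERT_TYPE_ORDER:
            for action in ("cancel", "override", "reprogram"):
                if at in by_resp.index and action in by_resp.columns:
                    table.loc[at, action] = int(by_resp.loc[at, action])
        table["total"] = table[years].sum(axis=1)
        table.loc["total"] = table.loc[ALERT_TYPE_ORDER].sum(axis=0)
    table.index.name = "alert_type"
    return table


def verify_conservation(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    table: pd.DataFrame | None = None,
    paired: pd.DataFrame | None = None,
) -> dict[str, int]:
    """Assert the alert-count conservation identities for a log.

    Total alerts must equal the sum over threshold types, the sum over years,
    and the sum over responses plus unresolved alerts; hard-limit rows must
    show zero overrides and reprograms. Raises :class:`ConservationError`
    with a diagnostic on failure, otherwise returns the tallies.
    """
    frame = as_frame(log)
    paired = pair_alerts(frame) if paired is None else paired
    table = threshold_violation_table(frame, paired=paired) if table is None else table
    n_alerts = int((frame["event_type"] == EventType.ALERT.value).sum())
    years = [c for c in table.columns if isinstance(c, (int, np.integer))]
    by_type = int(table.loc[ALERT_TYPE_ORDER, "total"].sum())
    by_year = int(table.loc["total", years].sum()) if years else 0
    by_response = int(table.loc["total", ["cancel", "override", "reprogram"]].sum())
    n_unresolved = int(paired["response"].isna().sum())
    tallies = {
        "total_alerts": n_alerts,
        "sum_over_types": by_type,
        "sum_over_years": by_year,
        "sum_over_responses": by_response,
        "unresolved": n_unresolved,
    }
    problems = []
    if by_type != n_alerts:
        problems.append(f"sum over types {by_type} != total alerts {n_alerts}")
    if by_year != n_alerts:
        problems.append(f"sum over years {by_year} != total alerts {n_alerts}")
    if by_response + n_unresolved != n_alerts:
        problems.append(
            f"responses {by_response} + unresolved {n_unresolved} != total alerts {n_alerts}"
        )
    for at in ("hard_min", "hard_max"):
        for action in ("override", "reprogram"):
            if int(table.loc[at, action]) != 0:
                problems.append(f"{at} row has nonzero {action} count")
    if problems:
        raise ConservationError("; ".join(problems))
    return tallies


# ---------------------------------------------------------------------------
# Burden by time and by medication
# ---------------------------------------------------------------------------

def burden_by_time(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    scheme: ShiftScheme = DEFAULT_SHIFT_SCHEME,
) -> dict[str, pd.DataFrame]:
    """Alert burden stratified by shift, day of week, weekend, and month.

    Returns four tables. Shift/day/weekend tables carry the alert count, the
    share of all alerts (summing to 100%), and the in-stratum alert rate
    (alerts in stratum / starts in stratum x 100, the per-start convention).
    The monthly table is a count series of alerts and starts for clustering
    inspection.
    """
    frame = as_frame(log)
    is_alert = frame["event_type"] == EventType.ALERT.value
    is_start = frame["event_type"] == EventType.INFUSION_START.value
    hours = frame["timestamp"].dt.hour

    strata = {
        "shift": scheme.assign(hours),
        "day_of_week": frame["timestamp"].dt.day_name(),
        "weekend": np.where(frame["timestamp"].dt.dayofweek >= 5, "weekend", "weekday"),
        "month": frame["timestamp"].dt.to_period("M").astype(str),
    }
    order = {
        "shift": scheme.labels,
        "day_of_week": ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"],
        "weekend": ["weekday", "weekend"],
    }
    out: dict[str, pd.DataFrame] = {}
    total_alerts = int(is_alert.sum())
    for name, labels in strata.items():
        labels = pd.Series(np.asarray(labels), index=frame.index)
        alert_counts = labels[is_alert].value_counts()
        start_counts = labels[is_start].value_counts()
        idx = order.get(name, sorted(set(labels.dropna())))
        table = pd.DataFrame(index=pd.Index(idx, name=name))
        table["n_alerts"] = [int(alert_counts.get(i, 0)) for i in idx]
        table["n_starts"] = [int(start_counts.get(i, 0)) for i in idx]
        table["pct_of_alerts"] = (
            100.0 * table["n_alerts"] / total_alerts if total_alerts else np.nan
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            table["pct_starts_with_alerts"] = np.where(
                table["n_starts"] > 0, 100.0 * table["n_alerts"] / table["n_starts"], np.nan
            )
        out[name] = table
    return out


def alerts_per_infusion_histogram(
    log: pd.DataFrame | Sequence[SmartPumpRecord], tail_from: int = 4
) -> pd.DataFrame:
    """Distribution of alert counts over infusions that alerted at least once.

    Buckets 1, 2, ..., ``tail_from - 1`` and a pooled ``>=tail_from`` tail;
    fractions sum to 1. An empty table is returned when no infusion alerted.
    """
    frame = as_frame(log)
    alerts = frame[frame["event_type"] == EventType.ALERT.value]
    if alerts.empty:
        return pd.DataFrame(columns=["n_infusions", "fraction"])
    per_infusion = alerts.groupby("infusion_id", sort=False).size()
    buckets = [str(k) for k in range(1, tail_from)] + [f">={tail_from}"]
    counts = {b: 0 for b in buckets}
    for c in per_infusion:
        key = str(c) if c < tail_from else f">={tail_from}"
        counts[key] += 1
    table = pd.DataFrame({"n_infusions": pd.Series(counts)}).loc[buckets]
    table["fraction"] = table["n_infusions"] / table["n_infusions"].sum()
    table.index.name = "alerts_per_infusion"
    return table


def burden_by_medication(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    k: int | None = 6,
    paired: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-drug alert burden, ranked by alerts per infusion start.

    Columns: alert count, start count, alerts per 100 starts, share of all
    alerts, override rate among resolved alerts, salience, and the share of a
    drug's alerting infusions that alerted more than once. ``k`` keeps the
    top-k alerting medications (None keeps all). Drugs with zero starts are
    ranked by raw alert count.
    """
    frame = as_frame(log)
    alerts = frame[frame["event_type"] == EventType.ALERT.value]
    starts = frame[frame["event_type"] == EventType.INFUSION_START.value]
    paired = pair_alerts(frame) if paired is None else paired
    resolved = paired.dropna(subset=["response"])

    drugs = sorted(set(alerts["drug_name"]) | set(starts["drug_name"]))
    total_alerts = len(alerts)
    rows = {}
    for drug in drugs:
        da = alerts[alerts["drug_name"] == drug]
        n_alerts = len(da)
        n_starts = int((starts["drug_name"] == drug).sum())
        dr = resolved[resolved["drug_name"] == drug]
        n_res = len(dr)
        n_override = int((dr["response"] == ResponseAction.OVERRIDE.value).sum())
        per_inf = da.groupby("infusion_id", sort=False).size()
        n_alerting_inf = len(per_inf)
        rows[drug] = {
            "n_alerts": n_alerts,
            "n_starts": n_starts,
            "alerts_per_100_starts": 100.0 * n_alerts / n_starts if n_starts else np.nan,
            "pct_of_all_alerts": 100.0 * n_alerts / total_alerts if total_alerts else np.nan,
            "override_rate": n_override / n_res if n_res else np.nan,
            "salience": 1.0 - n_override / n_res if n_res else np.nan,
            "multi_alert_share": float((per_inf > 1).sum()) / n_alerting_inf
            if n_alerting_inf
            else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "drug_name"
    if table.empty:
        return table
    table = table.sort_values(
        ["alerts_per_100_starts", "n_alerts"], ascending=False, na_position="last"
    )
    # drugs with alerts but no recorded starts float to the top by raw count
    no_starts = table["alerts_per_100_starts"].isna() & (table["n_alerts"] > 0)
    table = pd.concat([table[no_starts], table[~no_starts]])
    if k is not None:
        table = table.head(k)
    return table


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def chi_square_trend(
    successes: Sequence[float],
    totals: Sequence[float],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran–Armitage chi-square test for a linear trend in proportions.

    ``successes[i] / totals[i]`` are the per-group proportions of >=2 ordered
    groups; ``scores`` default to equally spaced 0, 1, 2, .... Returns the
    score statistic (chi-square with 1 df under the no-trend null) and the
    two-sided p-value. Degenerate pooled proportions (0 or 1) carry no trend
    information and return (0.0, 1.0).
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need >=2 ordered groups of matching shape")
    if np.any(n <= 0):
        raise ValueError("every group total must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("successes must satisfy 0 <= successes <= totals")
    s = np.arange(x.size, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.shape != x.shape:
        raise ValueError("scores must match the number of groups")
    N = n.sum()
    p = x.sum() / N
    if p in (0.0, 1.0):
        return 0.0, 1.0
    num = float((s * (x - n * p)).sum()) ** 2
    den = p * (1.0 - p) * float((n * s**2).sum() - (n * s).sum() ** 2 / N)
    if den == 0:
        return 0.0, 1.0
    statistic = num / den
    return statistic, float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

REPORT_TABLES = (
    "infusion_alert_summary",
    "ders_compliance",
    "response_distribution",
    "threshold_violations",
    "salience_by_drug",
    "burden_by_shift",
    "burden_by_day",
    "burden_by_weekend",
    "burden_by_month",
    "burden_by_medication",
    "alerts_per_infusion",
    "trend_tests",
)


@dataclass
class MetricReport:
    """The complete measure suite for one log, as named tables."""

    infusion_alert_summary: pd.DataFrame
    ders_compliance: pd.DataFrame
    response_distribution: pd.DataFrame
    threshold_violations: pd.DataFrame
    salience_by_drug: pd.DataFrame
    burden_by_shift: pd.DataFrame
    burden_by_day: pd.DataFrame
    burden_by_weekend: pd.DataFrame
    burden_by_month: pd.DataFrame
    burden_by_medication: pd.DataFrame
    alerts_per_infusion: pd.DataFrame
    trend_tests: pd.DataFrame
    salience_overall: float = float("nan")
    conservation: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in REPORT_TABLES}

    def write(self, out_dir: str | Path, formats: Sequence[str] = ("csv", "json")) -> list[Path]:
        """Write one file per table; percentages rounded to one decimal in CSV
        display copies, full precision in JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, table in self.tables().items():
            if "csv" in formats:
                p = out_dir / f"{name}.csv"
                display = table.copy()
                for col in display.columns:
                    if str(col).startswith("pct"):
                        display[col] = display[col].astype(float).round(1)
                display.to_csv(p)
                written.append(p)
            if "json" in formats:
                p = out_dir / f"{name}.json"
                table.to_json(p, orient="split", indent=2)
                written.append(p)
        if "json" in formats:
            p = out_dir / "summary.json"
            with p.open("w", encoding="utf-8") as fh:
                json.dump(
                    {"salience_overall": self.salience_overall, "conservation": self.conservation},
                    fh,
                    indent=2,
                )
            written.append(p)
        return written


def compute_report(
    log: pd.DataFrame | Sequence[SmartPumpRecord],
    scheme: ShiftScheme = DEFAULT_SHIFT_SCHEME,
    top_k: int | None = None,
) -> MetricReport:
    """Compute every measure for a log and verify conservation identities."""
    frame = as_frame(log)
    paired = pair_alerts(frame)
    table = threshold_violation_table(frame, paired=paired)
    conservation = verify_conservation(frame, table=table, paired=paired)
    freq = alert_frequency(frame)
    by_time = burden_by_time(frame, scheme)

    trend_rows = {}
    years = [y for y in freq.index if y != "all_years"]
    if len(years) >= 2:
        yearly = freq.loc[years]
        candidates = {
            "infusions_with_alerts": (
                yearly["n_infusions_with_alerts"], yearly["n_unique_infusions"]
            ),
            "alerts_per_start": (yearly["n_alerts"], yearly["n_infusion_starts"]),
        }
        resolved = paired.dropna(subset=["response"])
        if len(resolved):
            by_year = resolved.groupby("year").agg(
                n=("response", "size"),
                n_override=("response", lambda s: int((s == "override").sum())),
            )
            by_year = by_year.reindex([int(y) for y in years]).dropna()
            if len(by_year) >= 2:
                candidates["override_share"] = (by_year["n_override"], by_year["n"])
        for name, (succ, tot) in candidates.items():
            try:
                stat, p = chi_square_trend(succ.to_numpy(float), tot.to_numpy(float))
                trend_rows[name] = {"statistic": stat, "p_value": p}
            except ValueError as exc:
                logger.warning("trend test %s skipped: %s", name, exc)
    trend = pd.DataFrame.from_dict(trend_rows, orient="index")
    trend.index.name = "quantity"

    return MetricReport(
        infusion_alert_summary=freq,
        ders_compliance=ders_compliance(frame),
        response_distribution=response_distribution(frame, by="year", paired=paired),
        threshold_violations=table,
        salience_by_drug=alert_salience(frame, by="drug_name", paired=paired)
        if len(paired)
        else pd.DataFrame(columns=["n_resolved_alerts", "salience"]),
        burden_by_shift=by_time["shift"],
        burden_by_day=by_time["day_of_week"],
        burden_by_weekend=by_time["weekend"],
        burden_by_month=by_time["month"],
        burden_by_medication=burden_by_medication(frame, k=top_k, paired=paired),
        alerts_per_infusion=alerts_per_infusion_histogram(frame),
        trend_tests=trend,
        salience_overall=alert_salience(frame, by=None, paired=paired),
        conservation=conservation,
    )
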