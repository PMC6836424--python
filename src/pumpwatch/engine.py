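"""Dose-error-reduction-software (DERS) limit checking and response logic.

The engine answers three questions a smart pump must answer at programming
time: does the programmed dose violate a library limit and, if so, which one
(:func:`check_program`); which clinician responses does the violated limit
permit (:func:`allowed_responses` — hard limits force cancellation, soft
limits can additionally be overridden or reprogrammed); and what state does
the pump end up in after the response (:func:`apply_response`, which re-checks
reprogrammed doses so that a single programming episode can raise a chain of
alerts).

Severity precedence when several limits are violated at once: hard max, then
soft max, then hard min, then soft min — one alert per check, the most severe
maximum violation first. Comparisons are strict: a dose exactly equal to a
limit is within range. Limits absent from the library entry never fire, and
basic mode bypasses checking entirely.

Percent variance quantifies the magnitude of a violation as
``dose / limit * 100``, so a dose of 29x the hard maximum is a variance of
2900%; the excess over the limit (variance − 100) is exposed separately for
"% above the limit" phrasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import AlertEvent, AlertType, DoseUnit, DrugLibraryEntry, Mode, ResponseAction

__all__ = [
    "LimitCheckResult",
    "ProgrammingStatus",
    "ProgrammingOutcome",
    "UnitMismatchError",
    "ForcedCancelError",
    "check_program",
    "allowed_responses",
    "percent_variance",
    "excess_over_limit",
    "apply_response",
]


class UnitMismatchError(ValueError):
    """Programmed dose unit differs from the library entry's unit."""


class ForcedCancelError(ValueError):
    """A response other than cancel was attempted on a hard-limit alert."""


@dataclass(frozen=True)
class LimitCheckResult:
    """Outcome of checking one programmed dose against one library entry.

    ``alert_type`` is ``AlertType.NONE`` exactly when no limit is violated;
    then ``violated_limit`` and ``percent_variance`` are ``None``. For max
    violations the variance exceeds 100%, for min violations it is below.
    """

    alert_type: AlertType
    violated_limit: float | None = None
    percent_variance: float | None = None

    @property
    def alerted(self) -> bool:
        return self.alert_type is not AlertType.NONE


NO_ALERT = LimitCheckResult(AlertType.NONE)


def percent_variance(dose: float, limit: float) -> float:
    """Magnitude of a dose relative to a limit, as a percentage.

    ``percent_variance(29.0, 1.0) == 2900.0``: a dose of 29x the limit is a
    2900% variance. Scale-invariant in (dose, limit) jointly.
    """
    if limit <= 0:
        raise ValueError(f"limit must be positive, got {limit}")
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    return dose / limit * 100.0


def excess_over_limit(dose: float, limit: float) -> float:
    """Percent by which a dose exceeds (positive) or falls short of a limit."""
    return percent_variance(dose, limit) - 100.0


def check_program(
    dose: float,
    entry: DrugLibraryEntry,
    mode: Mode = Mode.DERS,
    dose_unit: DoseUnit | None = None,
) -> LimitCheckResult:
    """Classify a programmed dose against a library entry's limits.

    Returns exactly one of five outcomes (hard_max, soft_max, hard_min,
    soft_min, none). Basic mode always returns no alert. ``dose_unit``, when
    given, must match the entry's unit.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if dose_unit is not None and dose_unit is not entry.dose_unit:
        raise UnitMismatchError(
            f"{entry.drug_name}: programmed in {dose_unit.value} but library "
            f"limits are in {entry.dose_unit.value}"
        )
    if mode is Mode.BASIC:
        return NO_ALERT
    if entry.hard_max is not None and dose > entry.hard_max:
        return LimitCheckResult(AlertType.HARD_MAX, entry.hard_max, percent_variance(dose, entry.hard_max))
    if entry.soft_max is not None and dose > entry.soft_max:
        return LimitCheckResult(AlertType.SOFT_MAX, entry.soft_max, percent_variance(dose, entry.soft_max))
    if entry.hard_min is not None and dose < entry.hard_min and entry.hard_min > 0:
        return LimitCheckResult(AlertType.HARD_MIN, entry.hard_min, percent_variance(dose, entry.hard_min))
    if entry.soft_min is not None and dose < entry.soft_min and entry.soft_min > 0:
        return LimitCheckResult(AlertType.SOFT_MIN, entry.soft_min, percent_variance(dose, entry.soft_min))
    return NO_ALERT


HARD_RESPONSES = frozenset({ResponseAction.CANCEL})
SOFT_RESPONSES = frozenset(
    {ResponseAction.OVERRIDE, ResponseAction.CANCEL, ResponseAction.REPROGRAM}
)


def allowed_responses(alert_type: AlertType) -> frozenset[ResponseAction]:
    """Responses the pump permits for an alert type.

    Hard limits force cancellation; soft limits allow override, cancel, or
    reprogram.
    """
    if alert_type is AlertType.NONE:
        raise ValueError("no alert was raised; there is nothing to respond to")
    return HARD_RESPONSES if alert_type.is_hard else SOFT_RESPONSES


class ProgrammingStatus(str, Enum):
    RUNNING = "running"      # infusion proceeds at the resolved dose
    CANCELLED = "cancelled"  # programming abandoned
    ALERTED = "alerted"      # reprogrammed dose raised a further alert


@dataclass(frozen=True)
class ProgrammingOutcome:
    """Pump state after a clinician responds to an alert."""

    status: ProgrammingStatus
    dose: float | None = None
    follow_up: LimitCheckResult | None = None


def apply_response(
    alert: AlertEvent,
    action: ResponseAction,
    entry: DrugLibraryEntry,
    new_dose: float | None = None,
) -> ProgrammingOutcome:
    """Resolve an alert with a clinician action.

    * override — the infusion proceeds at the attempted dose (soft alerts
      only; overriding a hard limit raises :class:`ForcedCancelError`);
    * cancel — programming is terminated;
    * reprogram — ``new_dose`` is passed back through :func:`check_program`
      and may itself alert, yielding a multi-alert programming episode.
    """
    alert_type = alert.record.alert_type
    permitted = allowed_responses(alert_type)
    if action not in permitted:
        if alert_type.is_hard:
            raise ForcedCancelError(
                f"{action.value} not permitted on a {alert_type.value} alert; "
                "the pump forces cancellation"
            )
        raise ValueError(f"{action.value} not permitted for {alert_type.value} alerts")
    if action is ResponseAction.OVERRIDE:
        return ProgrammingOutcome(ProgrammingStatus.RUNNING, dose=alert.attempted_dose)
    if action is ResponseAction.CANCEL:
        return ProgrammingOutcome(ProgrammingStatus.CANCELLED)
    # reprogram
    if new_dose is None:
        raise ValueError("reprogram requires a new dose")
    recheck = check_program(new_dose, entry, mode=alert.record.mode)
    if recheck.alerted:
        return ProgrammingOutcome(ProgrammingStatus.ALERTED, dose=new_dose, follow_up=recheck)
    return ProgrammingOutcome(ProgrammingStatus.RUNNING, dose=new_dose)
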