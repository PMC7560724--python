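"""Longitudinal health-utility trajectories and QALY computation.

A patient's health utility is observed at up to three scheduled timepoints
(baseline, pre-surgery, post-surgery).  The *actual* QALY is the area under
the utility-versus-time curve over a fixed analysis window; the
*theoretical* QALY assumes the baseline utility would have persisted
unchanged over the same window; their difference is the *Lost QALY*
(negative values denote a net gain in quality-adjusted time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, ValidationError

#: Lower bound of the utility scale (worst health state valued below dead).
UTILITY_FLOOR = -0.022
#: Upper bound of the utility scale (full health).
UTILITY_CEILING = 1.0
#: Numerical tolerance for bound checks; violations within this are clamped.
BOUND_TOL = 1e-9


class Timepoint(str, Enum):
    """Scheduled assessment occasions in the treatment window."""

    BASELINE = "baseline"
    PRE_SURGERY = "pre_surgery"
    POST_SURGERY = "post_surgery"


#: Canonical chronological order of the three timepoints.
TIMEPOINT_ORDER = (Timepoint.BASELINE, Timepoint.PRE_SURGERY, Timepoint.POST_SURGERY)


class Integration(str, Enum):
    """How utility is interpolated between observations."""

    TRAPEZOID = "trapezoid"
    STEP_LOCF = "step_locf"


class Extension(str, Enum):
    """How the curve is extended past the last observation."""

    LOCF = "locf"
    TRUNCATE = "truncate"


def _check_utility(value: float, floor: float, ceiling: float, context: str = "") -> float:
    """Validate *value* against [floor, ceiling]; clamp sub-tolerance overshoot."""
    if not math.isfinite(value):
        raise ValidationError(f"utility must be finite, got {value!r}{context}")
    if value < floor - BOUND_TOL or value > ceiling + BOUND_TOL:
        raise ValidationError(
            f"utility {value} outside allowed range [{floor}, {ceiling}]{context}"
        )
    return min(max(value, floor), ceiling)


@dataclass(frozen=True)
class UtilityObservation:
    """One utility measurement for one patient at one timepoint.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    timepoint : Timepoint
        Scheduled occasion label.
    day : int
        Days elapsed since baseline (baseline itself is day 0).
    utility : float
        Health utility in ``[UTILITY_FLOOR, UTILITY_CEILING]``.
    """

    patient_id: str
    timepoint: Timepoint
    day: int
    utility: float

    def __post_init__(self) -> None:
        tp = Timepoint(self.timepoint)
        object.__setattr__(self, "timepoint", tp)
        if self.day < 0:
            raise ValidationError(
                f"day must be non-negative, got {self.day} "
                f"(patient {self.patient_id}, {tp.value})"
            )
        if tp is Timepoint.BASELINE and self.day != 0:
            raise ValidationError(
                f"baseline observation must have day 0, got day {self.day} "
                f"(patient {self.patient_id})"
            )
        u = _check_utility(
            float(self.utility),
            UTILITY_FLOOR,
            UTILITY_CEILING,
            context=f" (patient {self.patient_id}, {tp.value}, day {self.day})",
        )
        object.__setattr__(self, "utility", u)


@dataclass(frozen=True)
class PatientTrajectory:
    """Day-sorted utility observations for a single patient.

    ``complete`` is True iff all three scheduled timepoints are present.
    """

    patient_id: str
    observations: tuple[UtilityObservation, ...]
    complete: bool = field(init=False)

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        if not obs:
            raise ValidationError(f"patient {self.patient_id}: empty trajectory")
        days = [o.day for o in obs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: observation days must be strictly "
                f"increasing, got {days}"
            )
        labels = [o.timepoint for o in obs]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"patient {self.patient_id}: duplicate timepoint labels {labels}"
            )
        if labels[0] is not Timepoint.BASELINE:
            raise ValidationError(
                f"patient {self.patient_id}: first observation must be baseline, "
                f"got {labels[0].value}"
            )
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "complete", set(labels) == set(TIMEPOINT_ORDER))

    @property
    def baseline_utility(self) -> float:
        return self.observations[0].utility

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(o.day for o in self.observations)

    @property
    def utilities(self) -> tuple[float, ...]:
        return tuple(o.utility for o in self.observations)


@dataclass(frozen=True)
class QalyConfig:
    """Integration window and policies for QALY computation.

    window_years
        Length of the analysis window (default 0.5, i.e. six months).
    days_per_year
        Day-to-year conversion constant.
    integration
        Interpolation between observations: trapezoid (piecewise linear)
        or left-constant steps.
    extension
        Behaviour past the last observation: carry the last utility to the
        window end, or stop integrating at the last observation.
    """

    window_years: float = 0.5
    days_per_year: float = 365.25
    integration: Integration = Integration.TRAPEZOID
    extension: Extension = Extension.LOCF
    utility_floor: float = UTILITY_FLOOR
    utility_ceiling: float = UTILITY_CEILING

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise ConfigError(f"window_years must be > 0, got {self.window_years}")
        if self.days_per_year <= 0:
            raise ConfigError(f"days_per_year must be > 0, got {self.days_per_year}")
        if self.utility_floor >= self.utility_ceiling:
            raise ConfigError(
                f"utility_floor ({self.utility_floor}) must be below "
                f"utility_ceiling ({self.utility_ceiling})"
            )
        object.__setattr__(self, "integration", Integration(self.integration))
        object.__setattr__(self, "extension", Extension(self.extension))

    @property
    def window_days(self) -> float:
        return self.window_years * self.days_per_year


@dataclass(frozen=True)
class QalyResult:
    """Actual, theoretical, and Lost QALYs (in QALY-years) for one patient."""

    patient_id: str
    actual_qaly: float
    theoretical_qaly: float
    lost_qaly: float

    def __post_init__(self) -> None:
        expected = self.theoretical_qaly - self.actual_qaly
        if abs(self.lost_qaly - expected) > 1e-12:
            raise ValidationError(
                f"patient {self.patient_id}: lost_qaly {self.lost_qaly} != "
                f"theoretical - actual = {expected}"
            )


def build_trajectory(rows: Iterable[UtilityObservation]) -> PatientTrajectory:
    """Assemble and validate a :class:`PatientTrajectory` from observations.

    All rows must share one patient id.  Rows are sorted by day; duplicate
    timepoint labels, a non-zero baseline day, or out-of-range utilities are
    rejected with the offending row identified.
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("cannot build trajectory from zero observations")
    ids = {r.patient_id for r in rows}
    if len(ids) != 1:
        raise ValidationError(f"rows span multiple patient ids: {sorted(ids)}")
    rows.sort(key=lambda r: r.day)
    return PatientTrajectory(patient_id=rows[0].patient_id, observations=tuple(rows))


def compute_actual_qaly(trajectory: PatientTrajectory, config: QalyConfig) -> float:
    """Area under the utility-time curve over ``[0, window_years]``.

    Between observations the curve is piecewise linear (TRAPEZOID) or
    left-constant (STEP_LOCF); past the last observation the last utility is
    carried to the window end (LOCF) or integration stops (TRUNCATE).
    """
    if not trajectory.complete:
        missing = set(TIMEPOINT_ORDER) - {o.timepoint for o in trajectory.observations}
        raise ValidationError(
            f"patient {trajectory.patient_id}: incomplete trajectory "
            f"(missing {sorted(m.value for m in missing)})"
        )
    t = np.asarray(trajectory.days, dtype=float) / config.days_per_year
    u = np.asarray(trajectory.utilities, dtype=float)
    window = config.window_years
    if t[-1] > window + BOUND_TOL:
        raise ValidationError(
            f"patient {trajectory.patient_id}: observation at day "
            f"{trajectory.days[-1]} lies beyond the "
            f"{config.window_days:.1f}-day analysis window"
        )
    if config.integration is Integration.TRAPEZOID:
        area = float(np.trapezoid(u, t))
    else:  # STEP_LOCF
        area = float(np.sum(u[:-1] * np.diff(t)))
    if config.extension is Extension.LOCF:
        area += float(u[-1]) * (window - float(t[-1]))
    return area


def compute_theoretical_qaly(baseline_utility: float, config: QalyConfig) -> float:
    """QALYs had the baseline utility persisted over the whole window."""
    u = _check_utility(float(baseline_utility), config.utility_floor, config.utility_ceiling)
    return u * config.window_years


def compute_lost_qaly(theoretical: float, actual: float) -> float:
    """Theoretical minus actual QALYs; negative values are net gains."""
    if not (math.isfinite(theoretical) and math.isfinite(actual)):
        raise ValidationError(
            f"QALY inputs must be finite, got theoretical={theoretical}, actual={actual}"
        )
    return theoretical - actual


def compute_qaly_result(trajectory: PatientTrajectory, config: QalyConfig) -> QalyResult:
    """Convenience wrapper chaining actual, theoretical, and lost QALYs."""
    actual = compute_actual_qaly(trajectory, config)
    theoretical = compute_theoretical_qaly(trajectory.baseline_utility, config)
    return QalyResult(
        patient_id=trajectory.patient_id,
        actual_qaly=actual,
        theoretical_qaly=theoretical,
        lost_qaly=compute_lost_qaly(theoretical, actual),
    )
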