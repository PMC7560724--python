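"""Composite efficacy-toxicity score (QoLI).

Residual Cancer Burden (RCB, efficacy) and Lost QALY (toxicity burden) are
each normalized by a study-derived maximum, summed, and negated, so that a
higher score means better quality-of-life-adjusted clinical efficacy:

    qoli = -(rcb / max_rcb + lost_qaly / max_lost_qaly)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import QalyResult
from .errors import ConfigError, ValidationError

#: Default normalization constants (study-derived, overridable via QoliConfig).
DEFAULT_MAX_RCB = 4.35
DEFAULT_MAX_LOST_QALY = 0.54

_RCB_TOL = 1e-9


@dataclass(frozen=True)
class EfficacyRecord:
    """Residual Cancer Burden index for one patient (0 = pathological CR)."""

    patient_id: str
    rcb: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rcb):
            raise ValidationError(f"patient {self.patient_id}: rcb must be finite")
        if self.rcb < -_RCB_TOL:
            raise ValidationError(
                f"patient {self.patient_id}: rcb must be >= 0, got {self.rcb}"
            )
        object.__setattr__(self, "rcb", max(float(self.rcb), 0.0))


@dataclass(frozen=True)
class QoliConfig:
    """Normalization denominators for the composite score.

    Both defaults are maxima observed in the originating study cohort, not
    universal constants; raise them explicitly for cohorts that exceed them.
    """

    max_rcb: float = DEFAULT_MAX_RCB
    max_lost_qaly: float = DEFAULT_MAX_LOST_QALY

    def __post_init__(self) -> None:
        if self.max_rcb <= 0:
            raise ConfigError(f"max_rcb must be > 0, got {self.max_rcb}")
        if self.max_lost_qaly <= 0:
            raise ConfigError(f"max_lost_qaly must be > 0, got {self.max_lost_qaly}")


@dataclass(frozen=True)
class QoliResult:
    """Normalized proportions and composite score for one patient."""

    patient_id: str
    rcb_prop: float
    lost_qaly_prop: float
    qoli: float

    def __post_init__(self) -> None:
        expected = -(self.rcb_prop + self.lost_qaly_prop)
        if abs(self.qoli - expected) > 1e-12:
            raise ValidationError(
                f"patient {self.patient_id}: qoli {self.qoli} != "
                f"-(rcb_prop + lost_qaly_prop) = {expected}"
            )


def normalize_rcb(rcb: float, config: QoliConfig = QoliConfig()) -> float:
    """Map an RCB value onto [0, 1] by dividing by the configured maximum.

    Values above ``max_rcb`` are an error rather than being clamped: they
    signal data outside the range the normalization constant was derived
    from, and the caller must raise ``max_rcb`` explicitly.
    """
    if not math.isfinite(rcb):
        raise ValidationError(f"rcb must be finite, got {rcb!r}")
    if rcb < -_RCB_TOL:
        raise ValidationError(f"rcb must be >= 0, got {rcb}")
    if rcb > config.max_rcb + _RCB_TOL:
        raise ValidationError(
            f"rcb {rcb} exceeds max_rcb {config.max_rcb}; raise max_rcb "
            f"explicitly if this value is genuine"
        )
    return min(max(rcb, 0.0), config.max_rcb) / config.max_rcb


def normalize_lost_qaly(lost_qaly: float, config: QoliConfig = QoliConfig()) -> float:
    """Divide Lost QALY by the configured maximum; gains stay negative."""
    if not math.isfinite(lost_qaly):
        raise ValidationError(f"lost_qaly must be finite, got {lost_qaly!r}")
    return lost_qaly / config.max_lost_qaly


def compute_qoli(rcb_prop: float, lost_qaly_prop: float) -> float:
    """Negated sum of the two proportions; higher is better."""
    if not (math.isfinite(rcb_prop) and math.isfinite(lost_qaly_prop)):
        raise ValidationError(
            f"proportions must be finite, got ({rcb_prop!r}, {lost_qaly_prop!r})"
        )
    return -(rcb_prop + lost_qaly_prop)


def compute_patient_qoli(
    qaly: QalyResult,
    efficacy: EfficacyRecord,
    config: QoliConfig = QoliConfig(),
) -> QoliResult:
    """Chain normalization and composition for one patient."""
    if qaly.patient_id != efficacy.patient_id:
        raise ValidationError(
            f"patient id mismatch: QALY record {qaly.patient_id!r} vs "
            f"efficacy record {efficacy.patient_id!r}"
        )
    rcb_prop = normalize_rcb(efficacy.rcb, config)
    lost_prop = normalize_lost_qaly(qaly.lost_qaly, config)
    return QoliResult(
        patient_id=qaly.patient_id,
        rcb_prop=rcb_prop,
        lost_qaly_prop=lost_prop,
        qoli=compute_qoli(rcb_prop, lost_prop),
    )
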