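"""Utility layer: domain-score profiles, pluggable scorers, and imputation.

Utilities may be supplied directly, or derived from seven standardized
domain T-scores (mean 50, SD 10) via a scorer implementing
:class:`ScorerContract`.  The published preference-based scoring function is
deliberately *not* reimplemented here; it is injected by the user.  A
clearly-labelled rescaled-mean stub scorer is provided so the pipeline and
simulator can run end-to-end from domain scores.

Missing domains can be filled by ordinary-least-squares prediction from the
observed domains, fitted on complete reference profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np

from .core_model import BOUND_TOL, UTILITY_CEILING, UTILITY_FLOOR, Timepoint
from .errors import ValidationError

#: The seven domains a complete profile must carry, in canonical order.
DOMAINS = (
    "cognitive_function",
    "depression",
    "fatigue",
    "pain_interference",
    "physical_function",
    "sleep_disturbance",
    "social_roles",
)

#: Symptom domains where a higher T-score means *worse* health.
SYMPTOM_DOMAINS = frozenset(
    {"depression", "fatigue", "pain_interference", "sleep_disturbance"}
)

_MIN_REFERENCE_PROFILES = 10


def validate_utility(
    u: float,
    floor: float = UTILITY_FLOOR,
    ceiling: float = UTILITY_CEILING,
) -> float:
    """Return *u* if within ``[floor, ceiling]`` (1e-9 tolerance, clamped)."""
    if not math.isfinite(u):
        raise ValidationError(f"utility must be finite, got {u!r}")
    if u < floor - BOUND_TOL or u > ceiling + BOUND_TOL:
        raise ValidationError(
            f"utility {u} outside allowed range [{floor}, {ceiling}]"
        )
    return min(max(u, floor), ceiling)


@dataclass(frozen=True)
class DomainProfile:
    """Seven named domain T-scores for one patient at one timepoint.

    ``scores`` maps every domain in :data:`DOMAINS` to a float, or ``None``
    when that domain was not collected.  ``imputed`` records which domains
    were filled in by a model rather than observed.
    """

    patient_id: str
    timepoint: Timepoint
    scores: Mapping[str, float | None]
    imputed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        keys = set(self.scores)
        if keys != set(DOMAINS):
            extra = sorted(keys - set(DOMAINS))
            missing = sorted(set(DOMAINS) - keys)
            raise ValidationError(
                f"patient {self.patient_id}: profile domains must be exactly "
                f"{DOMAINS}; unknown={extra}, absent={missing}"
            )
        clean: dict[str, float | None] = {}
        for d in DOMAINS:
            v = self.scores[d]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                clean[d] = None
            elif math.isfinite(v):
                clean[d] = float(v)
            else:
                raise ValidationError(
                    f"patient {self.patient_id}: non-finite {d} score {v!r}"
                )
        if all(v is None for v in clean.values()):
            raise ValidationError(
                f"patient {self.patient_id}: profile has no observed domains"
            )
        object.__setattr__(self, "scores", clean)
        object.__setattr__(self, "imputed", frozenset(self.imputed))

    @property
    def missing_domains(self) -> tuple[str, ...]:
        return tuple(d for d in DOMAINS if self.scores[d] is None)

    @property
    def is_complete(self) -> bool:
        return not self.missing_domains


@runtime_checkable
class ScorerContract(Protocol):
    """Maps a complete :class:`DomainProfile` to a utility within bounds."""

    name: str

    def __call__(self, profile: DomainProfile) -> float: ...


@dataclass(frozen=True)
class RescaledMeanScorer:
    """Documented *stub* scorer — NOT the published preference function.

    Symptom-domain T-scores are direction-flipped (``100 - T``) so higher is
    uniformly better, averaged, and the assumed plausible T-score range
    ``[t_worst, t_best]`` is mapped affinely onto the utility bounds, then
    clipped.  Exists solely so tests and the simulator can exercise the
    domain-score path end to end.
    """

    name: str = "rescaled_mean_stub"
    t_worst: float = 20.0
    t_best: float = 80.0

    def __call__(self, profile: DomainProfile) -> float:
        aligned = [
            100.0 - profile.scores[d] if d in SYMPTOM_DOMAINS else profile.scores[d]
            for d in DOMAINS
        ]
        m = float(np.mean(aligned))
        frac = (m - self.t_worst) / (self.t_best - self.t_worst)
        u = UTILITY_FLOOR + frac * (UTILITY_CEILING - UTILITY_FLOOR)
        return min(max(u, UTILITY_FLOOR), UTILITY_CEILING)


@dataclass(frozen=True)
class PassthroughScorer:
    """Identity scorer returning precomputed utilities keyed by (patient, timepoint)."""

    utilities: Mapping[tuple[str, Timepoint], float]
    name: str = "passthrough"

    def __call__(self, profile: DomainProfile) -> float:
        key = (profile.patient_id, profile.timepoint)
        try:
            return float(self.utilities[key])
        except KeyError:
            raise ValidationError(
                f"no precomputed utility for patient {profile.patient_id} "
                f"at {profile.timepoint.value}"
            ) from None


@dataclass(frozen=True)
class ImputationModel:
    """OLS prediction of one domain's T-score from the other six."""

    target: str
    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    n_fit: int

    def __post_init__(self) -> None:
        if self.target in self.predictors:
            raise ValidationError(
                f"imputation model for {self.target} cannot use itself as predictor"
            )
        if len(self.coefficients) != len(self.predictors):
            raise ValidationError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.predictors)} predictors"
            )
        vals = (*self.coefficients, self.intercept)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite model parameters for {self.target}")

    def predict(self, profile: DomainProfile) -> float:
        x = []
        for p in self.predictors:
            v = profile.scores[p]
            if v is None:
                raise ValidationError(
                    f"patient {profile.patient_id}: predictor {p} for imputing "
                    f"{self.target} is itself missing"
                )
            x.append(v)
        return self.intercept + float(np.dot(self.coefficients, x))


def fit_imputation_model(
    reference: Iterable[DomainProfile], target: str
) -> ImputationModel:
    """Fit OLS of the *target* domain on the other six, over complete profiles.

    Deterministic: the same reference set reproduces coefficients exactly.
    """
    if target not in DOMAINS:
        raise ValidationError(f"unknown target domain {target!r}")
    complete = [p for p in reference if p.is_complete]
    if len(complete) < _MIN_REFERENCE_PROFILES:
        raise ValidationError(
            f"need >= {_MIN_REFERENCE_PROFILES} complete reference profiles to "
            f"fit an imputation model, got {len(complete)}"
        )
    predictors = tuple(d for d in DOMAINS if d != target)
    X = np.array([[p.scores[d] for d in predictors] for p in complete])
    y = np.array([p.scores[target] for p in complete])
    variances = X.var(axis=0)
    degenerate = [predictors[i] for i in np.flatnonzero(variances == 0)]
    if degenerate:
        raise ValidationError(
            f"degenerate (constant) predictors in reference set: {degenerate}"
        )
    design = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return ImputationModel(
        target=target,
        predictors=predictors,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        n_fit=len(complete),
    )


def complete_profile(
    profile: DomainProfile, models: Mapping[str, ImputationModel]
) -> DomainProfile:
    """Fill every missing domain of *profile* from its model; flag provenance.

    A profile with no missing domains is returned unchanged.
    """
    missing = profile.missing_domains
    if not missing:
        return profile
    uncovered = [d for d in missing if d not in models]
    if uncovered:
        raise ValidationError(
            f"patient {profile.patient_id}: no imputation model for missing "
            f"domain(s) {uncovered}"
        )
    scores = dict(profile.scores)
    for d in missing:
        scores[d] = models[d].predict(profile)
    return replace(
        profile, scores=scores, imputed=profile.imputed | frozenset(missing)
    )


def score_profile(profile: DomainProfile, scorer: ScorerContract) -> float:
    """Apply *scorer* to a complete profile and bound-check the result."""
    if not profile.is_complete:
        raise ValidationError(
            f"patient {profile.patient_id}: cannot score profile with missing "
            f"domains {profile.missing_domains}; impute first"
        )
    return validate_utility(scorer(profile))
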