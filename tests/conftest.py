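"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from qoli import PatientTrajectory, Timepoint, UtilityObservation, build_trajectory

TP = (Timepoint.BASELINE, Timepoint.PRE_SURGERY, Timepoint.POST_SURGERY)


def make_trajectory(
    days: tuple[int, ...],
    utilities: tuple[float, ...],
    patient_id: str = "p1",
) -> PatientTrajectory:
    rows = [
        UtilityObservation(patient_id, tp, d, u)
        for tp, d, u in zip(TP, days, utilities)
    ]
    return build_trajectory(rows)


def grid_qaly_oracle(
    days,
    utilities,
    window_years: float = 0.5,
    days_per_year: float = 365.25,
    extension: str = "locf",
    n_steps: int = 200_000,
) -> float:
    """Fine-grid trapezoid quadrature of the piecewise-linear utility curve.

    Deliberately independent of the package implementation: the curve is
    *sampled* pointwise on a dense grid (linear interpolation between
    observations, last value carried forward) and integrated numerically.
    """
    t = np.asarray(days, dtype=float) / days_per_year
    u = np.asarray(utilities, dtype=float)
    t_end = window_years if extension == "locf" else float(t[-1])
    grid = np.linspace(0.0, t_end, n_steps + 1)
    vals = np.interp(grid, t, u)  # np.interp holds edge values -> LOCF tail
    return float(np.trapezoid(vals, grid))


def step_qaly_oracle(
    days,
    utilities,
    window_years: float = 0.5,
    days_per_year: float = 365.25,
    extension: str = "locf",
    n_steps: int = 400_000,
) -> float:
    """Midpoint-rule quadrature of the left-constant step curve."""
    t = np.asarray(days, dtype=float) / days_per_year
    u = np.asarray(utilities, dtype=float)
    t_end = window_years if extension == "locf" else float(t[-1])
    edges = np.linspace(0.0, t_end, n_steps + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    idx = np.clip(np.searchsorted(t, mids, side="right") - 1, 0, len(u) - 1)
    return float(np.sum(u[idx]) * (t_end / n_steps))


def random_complete_trajectory(rng: np.random.Generator, patient_id: str = "p"):
    """Random valid 3-point trajectory within the default 6-month window."""
    d1 = int(rng.integers(1, 120))
    d2 = int(rng.integers(d1 + 1, 182))
    u = rng.uniform(-0.022, 1.0, size=3)
    return make_trajectory((0, d1, d2), tuple(u), patient_id)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_completion_cohort(
    n_baseline: int = 551, n_complete: int = 102
) -> dict[str, PatientTrajectory]:
    """Fixture cohort: n_complete patients with all three timepoints, the
    remainder with baseline only."""
    out: dict[str, PatientTrajectory] = {}
    for i in range(n_baseline):
        pid = f"pt{i:04d}"
        if i < n_complete:
            out[pid] = make_trajectory((0, 90, 150), (0.8, 0.6, 0.7), pid)
        else:
            out[pid] = build_trajectory(
                [UtilityObservation(pid, Timepoint.BASELINE, 0, 0.8)]
            )
    return out
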