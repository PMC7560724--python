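"""Arm-level aggregation: summary statistics, density grids, bootstrap contrasts.

Per-patient RCB / Lost QALY / QoLI values are reduced to per-arm descriptive
statistics and kernel-density grids (mirroring per-agent density panels),
plus an optional seeded bootstrap comparison of arm means.  The bootstrap
comparison is an artifact extension: the source analysis compares arm
densities descriptively only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Metrics summarized per arm.
METRICS = ("rcb", "lost_qaly", "qoli")

_MIN_DENSITY_N = 5
_GRID_SIZE = 256
_MIN_BOOT_REPLICATES = 100


@dataclass(frozen=True)
class MetricStats:
    """Sample statistics for one metric in one arm; ``sd`` is the n-1 form."""

    mean: float
    median: float
    sd: float | None
    min: float
    max: float


@dataclass(frozen=True)
class DensityGrid:
    """Gaussian KDE evaluated on an ordered abscissa grid."""

    x: tuple[float, ...]
    density: tuple[float, ...]
    bandwidth: float


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    n: int
    stats: dict[str, MetricStats]
    densities: dict[str, DensityGrid | None]


@dataclass(frozen=True)
class ArmComparison:
    """Difference in arm means with a seeded bootstrap percentile CI."""

    arm_a: str
    arm_b: str
    metric: str
    mean_difference: float
    level: float
    ci_lower: float
    ci_upper: float
    replicates: int
    seed: int


def _column(values: pd.DataFrame | np.ndarray, metric: str) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        if metric not in values.columns:
            raise ValidationError(
                f"unknown metric {metric!r}; available: {list(values.columns)}"
            )
        arr = values[metric].to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite values in metric {metric!r}")
    return arr


def export_density_grid(
    values: np.ndarray, bandwidth_rule: str = "silverman"
) -> DensityGrid:
    """Gaussian KDE on a 256-point grid spanning ``[min - 3h, max + 3h]``.

    ``h`` is the kernel bandwidth from *bandwidth_rule* (Silverman's rule by
    default).  Requires at least 5 distinct-variance observations.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("density export expects a 1-D sample")
    if len(arr) < _MIN_DENSITY_N:
        raise ValidationError(
            f"density export needs >= {_MIN_DENSITY_N} values, got {len(arr)}"
        )
    if np.ptp(arr) == 0:
        raise ValidationError(
            "density export undefined for an all-identical sample (zero bandwidth)"
        )
    kde = stats.gaussian_kde(arr, bw_method=bandwidth_rule)
    h = float(kde.factor * arr.std(ddof=1))
    x = np.linspace(arr.min() - 3 * h, arr.max() + 3 * h, _GRID_SIZE)
    return DensityGrid(
        x=tuple(float(v) for v in x),
        density=tuple(float(v) for v in kde(x)),
        bandwidth=h,
    )


def summarize_arm(arm: str, results: pd.DataFrame) -> ArmSummary:
    """Descriptive statistics (and KDE grids when n >= 5) for one arm.

    *results* is a per-patient table with columns ``rcb``, ``lost_qaly`` and
    ``qoli``.  SD is reported as missing for n = 1; degenerate (zero
    variance) densities are omitted with a logged note.
    """
    n = len(results)
    if n == 0:
        raise ValidationError(f"arm {arm!r}: cannot summarize an empty arm")
    stats_out: dict[str, MetricStats] = {}
    densities: dict[str, DensityGrid | None] = {}
    for metric in METRICS:
        arr = _column(results, metric)
        stats_out[metric] = MetricStats(
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            sd=float(arr.std(ddof=1)) if n > 1 else None,
            min=float(arr.min()),
            max=float(arr.max()),
        )
        if n >= _MIN_DENSITY_N and np.ptp(arr) > 0:
            densities[metric] = export_density_grid(arr)
        else:
            if n >= _MIN_DENSITY_N:
                log.info(
                    "arm %s metric %s: zero-variance sample, density omitted",
                    arm,
                    metric,
                )
            densities[metric] = None
    return ArmSummary(arm=arm, n=n, stats=stats_out, densities=densities)


def compare_arms(
    a: pd.DataFrame | np.ndarray,
    b: pd.DataFrame | np.ndarray,
    metric: str,
    replicates: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    arm_a: str = "a",
    arm_b: str = "b",
) -> ArmComparison:
    """``mean(a) - mean(b)`` with a seeded nonparametric bootstrap CI."""
    if replicates < _MIN_BOOT_REPLICATES:
        raise ValidationError(
            f"bootstrap needs >= {_MIN_BOOT_REPLICATES} replicates, got {replicates}"
        )
    xa = _column(a, metric)
    xb = _column(b, metric)
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError(
            f"both arms need n >= 2 for comparison, got {len(xa)} and {len(xb)}"
        )
    rng = np.random.default_rng(seed)
    boot_a = xa[rng.integers(0, len(xa), size=(replicates, len(xa)))].mean(axis=1)
    boot_b = xb[rng.integers(0, len(xb), size=(replicates, len(xb)))].mean(axis=1)
    diffs = boot_a - boot_b
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return ArmComparison(
        arm_a=arm_a,
        arm_b=arm_b,
        metric=metric,
        mean_difference=float(xa.mean() - xb.mean()),
        level=level,
        ci_lower=float(lo),
        ci_upper=float(hi),
        replicates=replicates,
        seed=seed,
    )


def summary_table(summaries: list[ArmSummary]) -> pd.DataFrame:
    """Flatten arm summaries into a tidy (arm, metric, statistics) table."""
    rows = []
    for s in summaries:
        for metric in METRICS:
            ms = s.stats[metric]
            rows.append(
                {
                    "arm": s.arm,
                    "metric": metric,
                    "n": s.n,
                    "mean": ms.mean,
                    "median": ms.median,
                    "sd": ms.sd if ms.sd is not None else np.nan,
                    "min": ms.min,
                    "max": ms.max,
                }
            )
    return pd.DataFrame(rows)


def density_table(summaries: list[ArmSummary]) -> pd.DataFrame:
    """Flatten density grids into a tidy (arm, metric, x, density) table."""
    rows = []
    for s in summaries:
        for metric in METRICS:
            grid = s.densities[metric]
            if grid is None:
                continue
            for x, d in zip(grid.x, grid.density):
                rows.append({"arm": s.arm, "metric": metric, "x": x, "density": d})
    return pd.DataFrame(rows, columns=["arm", "metric", "x", "density"])
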