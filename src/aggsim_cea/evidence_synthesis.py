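"""Pooling per-study utility changes into per-arm trajectories over time.

Main mode pools, at each grid time t, the studies whose duration equals t,
weighting by the total number of subjects N.  Sensitivity mode additionally
prorates longer studies down to t: a study of duration d >= t contributes
delta * (t/d) (the exact fraction, e.g. 3/36 rather than the rounded 8.3%).
Studies shorter than t never contribute in either mode.

Interval widths between grid points are expressed in years and, by default,
*truncated* (floored toward zero) at two decimals — 2 months -> 0.16 years,
1 month -> 0.08 years, a quarter -> 0.25.  This convention is what the
published QALY tables actually use; exact twelfths are available via
``year_fraction="exact"`` for users who prefer the unrounded arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .exceptions import EligibilityError, ValidationError
from .study_data import Formulation, StudyResult

MODES = ("main", "sensitivity")


def trunc2_years(months: int) -> float:
    """months/12 in years, floored toward zero at two decimals (exact arithmetic)."""
    return math.floor(Fraction(months, 12) * 100) / 100


def exact_years(months: int) -> float:
    return months / 12


_YEAR_FRACTIONS = {"trunc2": trunc2_years, "exact": exact_years}


@dataclass(frozen=True)
class PooledChange:
    """n-weighted pooled utility change for both arms at one time point."""

    t_months: int
    delta_active: float
    delta_placebo: float
    study_ids: tuple[str, ...]
    weights: tuple[float, ...]


@dataclass(frozen=True)
class TimePointEstimate:
    t_months: int
    year_fraction_width: float
    delta_active: float
    delta_placebo: float
    study_ids: tuple[str, ...]
    weights: tuple[float, ...]


@dataclass(frozen=True)
class Trajectory:
    """Utility-change polyline per arm, after an implicit (t=0, change 0) origin."""

    points: tuple[TimePointEstimate, ...]
    mode: str
    formulation: Formulation | None = None

    def __post_init__(self):
        ts = [p.t_months for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])) or (ts and ts[0] <= 0):
            raise ValidationError("grid times must be strictly increasing and > 0")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def grid(self) -> tuple[int, ...]:
        return tuple(p.t_months for p in self.points)

    def deltas(self, arm: str) -> tuple[float, ...]:
        attr = {"active": "delta_active", "placebo": "delta_placebo"}[arm]
        return tuple(getattr(p, attr) for p in self.points)


def _eligible(studies: Iterable[StudyResult], t_months: int, mode: str):
    if mode == "main":
        return [s for s in studies if s.duration_months == t_months]
    return [s for s in studies if s.duration_months >= t_months]


def pooled_change(
    studies: Iterable[StudyResult], t_months: int, mode: str = "main"
) -> PooledChange:
    """n-weighted pooled utility change at time ``t_months``.

    Main mode: mean over studies with duration == t.  Sensitivity mode: mean
    over studies with duration >= t of delta * t/duration.  Raises
    :class:`EligibilityError` (listing the available durations) when no study
    qualifies.
    """
    studies = list(studies)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    eligible = _eligible(studies, t_months, mode)
    if not eligible:
        raise EligibilityError(
            f"no study eligible at t={t_months} months in {mode} mode; available "
            f"durations: {sorted({s.duration_months for s in studies})}"
        )
    total_n = sum(s.n for s in eligible)
    weights = tuple(s.n / total_n for s in eligible)

    def prorate(s: StudyResult) -> float:
        return t_months / s.duration_months if mode == "sensitivity" else 1.0

    delta_active = sum(w * s.delta_active * prorate(s) for w, s in zip(weights, eligible))
    delta_placebo = sum(
        w * s.delta_placebo * prorate(s) for w, s in zip(weights, eligible)
    )
    return PooledChange(
        t_months=t_months,
        delta_active=delta_active,
        delta_placebo=delta_placebo,
        study_ids=tuple(s.study_id for s in eligible),
        weights=weights,
    )


def default_grid(studies: Iterable[StudyResult]) -> tuple[int, ...]:
    """Sorted distinct study durations — the natural grid of a study set."""
    return tuple(sorted({s.duration_months for s in studies}))


def build_trajectory(
    studies: Iterable[StudyResult],
    grid: Sequence[int] | None = None,
    mode: str = "main",
    year_fraction: str = "trunc2",
    formulation: Formulation | str | None = None,
) -> Trajectory:
    """Pooled utility-change trajectory over an increasing month grid.

    ``formulation`` optionally restricts the study set first.  Each interval
    width is the (by default trunc2) year fraction of t_k - t_{k-1}, with the
    origin at t=0.  Eligibility errors are annotated with the grid point.
    """
    studies = list(studies)
    if formulation is not None:
        formulation = Formulation.parse(formulation)
        studies = [s for s in studies if s.formulation == formulation]
    if grid is None:
        grid = default_grid(studies)
    grid = [int(t) for t in grid]
    if not grid or any(t2 <= t1 for t1, t2 in zip(grid, grid[1:])) or grid[0] <= 0:
        raise ValidationError("grid must be non-empty, strictly increasing and > 0")
    width_fn = _YEAR_FRACTIONS[year_fraction]

    points = []
    prev_t = 0
    for t in grid:
        try:
            pooled = pooled_change(studies, t, mode)
        except EligibilityError as exc:
            raise EligibilityError(f"grid point {t} months: {exc}") from exc
        points.append(
            TimePointEstimate(
                t_months=t,
                year_fraction_width=width_fn(t - prev_t),
                delta_active=pooled.delta_active,
                delta_placebo=pooled.delta_placebo,
                study_ids=pooled.study_ids,
                weights=pooled.weights,
            )
        )
        prev_t = t
    return Trajectory(points=tuple(points), mode=mode, formulation=formulation)
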