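"""QALY change by trapezoidal area under the utility-change trajectory.

The QALY change over a horizon is the integral of the piecewise-linear
utility-*change* curve (gain relative to baseline, starting at 0 at t=0)
against time in years:

    QALY(h) = sum over intervals up to h of 1/2 (d_prev + d_curr) * width.

Computing the area on changes rather than absolute utilities is what allows a
negative "QALY change" for an arm that deteriorates; an absolute-utility
variant is provided separately and is never used by the replication pipeline.
No discounting is applied at any horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evidence_synthesis import Trajectory
from .exceptions import GridError


@dataclass(frozen=True)
class QalyChange:
    arm: str
    horizon_months: int
    value: float


def qaly_auc(trajectory: Trajectory, horizon_months: int, arm: str = "active") -> QalyChange:
    """Trapezoid area of one arm's utility-change polyline up to ``horizon_months``.

    The horizon must be a grid point of the trajectory; the change at the
    implicit origin is exactly 0.
    """
    if horizon_months not in trajectory.grid:
        raise GridError(
            f"horizon {horizon_months} months is not a grid point; grid: "
            f"{trajectory.grid}"
        )
    total = 0.0
    prev_delta = 0.0
    for point in trajectory.points:
        delta = getattr(point, f"delta_{arm}")
        total += 0.5 * (prev_delta + delta) * point.year_fraction_width
        prev_delta = delta
        if point.t_months == horizon_months:
            break
    return QalyChange(arm=arm, horizon_months=horizon_months, value=total)


def qaly_auc_absolute(
    trajectory: Trajectory,
    horizon_months: int,
    arm: str,
    baseline_utility: float,
) -> QalyChange:
    """AUC of the absolute utility curve (baseline level + change). Non-default.

    Equals the change-based AUC plus baseline_utility times the elapsed
    year-fraction; provided for users who want absolute QALYs rather than
    QALY gains.
    """
    change = qaly_auc(trajectory, horizon_months, arm)
    elapsed = sum(
        p.year_fraction_width
        for p in trajectory.points
        if p.t_months <= horizon_months
    )
    return QalyChange(
        arm=arm,
        horizon_months=horizon_months,
        value=change.value + baseline_utility * elapsed,
    )
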