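"""Drug-cost accumulation, price-range trimming, ICER and dominance logic.

Prices are daily drug costs in EUR; placebo costs 0 by convention.  The
price range of a formulation is summarised by three values derived from a
list of observed country prices:

* ``high``  — mean of the prices after excluding those more than 50% *below*
  the overall average (p < 0.5*m dropped);
* ``low``   — mean after excluding prices more than 50% *above* the average
  (p > 1.5*m dropped);
* ``median``— sample median of the untrimmed list.

The ICER for an intervention vs its comparator is incremental cost divided by
incremental QALY.  A ratio is only meaningful when both increments have the
same strict sign; otherwise one strategy dominates ("Placebo better" when the
intervention costs more and yields no more QALYs).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError, ValidationError

#: Default calendar convention for turning daily prices into per-horizon costs.
DAYS_PER_MONTH_DEFAULT = 30.0


@dataclass(frozen=True)
class PriceRange:
    """Low/median/high daily price summary (EUR/day).

    The trimming procedure guarantees low <= overall mean <= high (removing
    below-average prices can only raise a mean, and vice versa), but the
    sample median of a skewed list may fall outside the trimmed band, so only
    ``low <= high`` is enforced.
    """

    low: float
    median: float
    high: float

    def __post_init__(self):
        if not (0 <= self.low <= self.high) or self.median < 0:
            raise ValidationError(
                f"prices must satisfy 0 <= low <= high and median >= 0, got "
                f"({self.low}, {self.median}, {self.high})"
            )


def price_range(prices: Sequence[float]) -> PriceRange:
    """Trimmed-mean price band plus median of a non-empty price list."""
    arr = np.asarray(list(prices), dtype=float)
    if arr.size == 0:
        raise InputError("price list must be non-empty")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise InputError("prices must be finite and non-negative")
    if np.all(arr == arr[0]):
        # No exclusion is possible; collapse exactly (no fp summation noise).
        p = float(arr[0])
        return PriceRange(low=p, median=p, high=p)
    m = arr.mean()
    high = arr[arr >= 0.5 * m].mean()
    low = arr[arr <= 1.5 * m].mean()
    return PriceRange(low=float(low), median=float(np.median(arr)), high=float(high))


def cost_at(
    price_per_day: float,
    t_months: int,
    days_per_month: float = DAYS_PER_MONTH_DEFAULT,
) -> float:
    """Cumulative drug cost (EUR) at ``t_months`` for a constant daily price."""
    if price_per_day < 0 or t_months < 0 or days_per_month < 0:
        raise InputError("price, months and days_per_month must be non-negative")
    return price_per_day * t_months * days_per_month


class Verdict(str, enum.Enum):
    RATIO = "ratio"
    COMPARATOR_DOMINATES = "comparator_dominates"
    INTERVENTION_DOMINATES = "intervention_dominates"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ICERResult:
    incremental_cost: float
    incremental_qaly: float
    verdict: Verdict
    icer: float | None = None
    horizon_months: int | None = None


def icer(
    cost_active: float,
    cost_placebo: float,
    qaly_active: float,
    qaly_placebo: float,
    horizon_months: int | None = None,
) -> ICERResult:
    """Incremental cost-effectiveness of the active arm vs the comparator.

    Dominance verdicts: the comparator dominates when the intervention is no
    more effective and no cheaper (incremental QALY <= 0 with incremental
    cost >= 0, not both zero); the intervention dominates in the mirrored
    case.  Both increments exactly zero is flagged indeterminate.  The ratio
    is reported only when the increments share a strict sign.
    """
    for v in (cost_active, cost_placebo, qaly_active, qaly_placebo):
        if not math.isfinite(v):
            raise InputError("costs and QALYs must be finite")
    d_cost = cost_active - cost_placebo
    d_qaly = qaly_active - qaly_placebo
    common = dict(
        incremental_cost=d_cost, incremental_qaly=d_qaly, horizon_months=horizon_months
    )
    if d_cost == 0 and d_qaly == 0:
        return ICERResult(verdict=Verdict.INDETERMINATE, **common)
    if d_qaly <= 0 and d_cost >= 0:
        return ICERResult(verdict=Verdict.COMPARATOR_DOMINATES, **common)
    if d_qaly >= 0 and d_cost <= 0:
        return ICERResult(verdict=Verdict.INTERVENTION_DOMINATES, **common)
    return ICERResult(verdict=Verdict.RATIO, icer=d_cost / d_qaly, **common)


class Classification(str, enum.Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINATED = "dominated"
    DOMINANT = "dominant"


#: Conventional European willingness-to-pay reference, EUR per QALY.
DEFAULT_WTP_THRESHOLD = 30_000.0


def classify(
    result: ICERResult, wtp_threshold: float = DEFAULT_WTP_THRESHOLD
) -> Classification:
    """Map an ICER result to a decision against a willingness-to-pay threshold."""
    if wtp_threshold <= 0:
        raise InputError("wtp_threshold must be positive")
    if result.verdict is Verdict.COMPARATOR_DOMINATES:
        return Classification.DOMINATED
    if result.verdict is Verdict.INTERVENTION_DOMINATES:
        return Classification.DOMINANT
    if result.verdict is Verdict.INDETERMINATE:
        raise InputError("an indeterminate comparison cannot be classified")
    return (
        Classification.COST_EFFECTIVE
        if result.icer <= wtp_threshold
        else Classification.NOT_COST_EFFECTIVE
    )
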