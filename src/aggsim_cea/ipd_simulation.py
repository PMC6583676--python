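"""Pseudo-IPD reconstruction: correlated normal draws with range rejection.

Published trials report only aggregate statistics.  To recover
individual-level variability, each arm/visit is modelled as a multivariate
normal over (pain, function, stiffness, age, years_since_oa) parameterised by
the published means, SDs and correlations; draws falling outside the
permissible clinical ranges are discarded and redrawn until the requested
number of in-range records is reached.

Two modelling notes (deliberate, documented rather than corrected):

* rejection is of the whole vector, never per-coordinate clipping — clipping
  would pile mass on the boundaries and bias the correlations;
* the published aggregates are treated as parameters of the *untruncated*
  normal, so the moments of the accepted sample differ slightly from the
  inputs whenever the boxes actually bind.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import CovarianceError, InfeasibilityError, ValidationError
from .study_data import VARIABLES, ArmAggregate

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-8

#: WOMAC subscales on the normalised 0-20/0-68/0-8 scales; age and disease
#: duration in years.
DEFAULT_LOWER = (0.0, 0.0, 0.0, 0.0, 0.0)
DEFAULT_UPPER = (20.0, 68.0, 8.0, 100.0, 100.0)


@dataclass(frozen=True)
class PermissibleRanges:
    """Closed per-variable acceptance boxes for the rejection sampler."""

    lower: np.ndarray = DEFAULT_LOWER
    upper: np.ndarray = DEFAULT_UPPER

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        k = len(VARIABLES)
        if lower.shape != (k,) or upper.shape != (k,):
            raise ValidationError(f"ranges must have length {k}")
        if np.any(lower > upper):
            raise ValidationError("each lower bound must be <= its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Row-wise in-box mask for an (n, 5) array."""
        values = np.atleast_2d(values)
        return np.all((values >= self.lower) & (values <= self.upper), axis=1)

    def widened(self, factor: float = np.inf) -> "PermissibleRanges":
        """Ranges widened symmetrically (``inf`` disables truncation)."""
        if np.isinf(factor):
            return PermissibleRanges(
                np.full(len(VARIABLES), -np.inf), np.full(len(VARIABLES), np.inf)
            )
        centre = (self.lower + self.upper) / 2
        half = (self.upper - self.lower) / 2 * factor
        return PermissibleRanges(centre - half, centre + half)


def nearest_psd(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped symmetric repair of a nearly-PSD matrix."""
    sym = (matrix + matrix.T) / 2
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    return (v * w) @ v.T


def sample_ipd(
    aggregate: ArmAggregate,
    n_sim: int,
    ranges: PermissibleRanges | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    covariance: np.ndarray | None = None,
    acceptance_floor: float = 1e-4,
    max_draws: int = 1_000_000,
    repair_psd: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_sim`` in-range patient records for one arm/visit.

    Returns a DataFrame with the five clinical columns plus ``female`` fixed
    to 1 (the utility mapping is evaluated for women).  The realised
    acceptance rate is stored in ``df.attrs["acceptance_rate"]``.

    ``covariance`` overrides the SD/correlation assembly for studies that
    publish a covariance matrix directly.  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValidationError(f"n_sim must be >= 1, got {n_sim}")
    ranges = ranges or PermissibleRanges()
    rng = np.random.default_rng(seed)

    mean = aggregate.means
    cov = np.asarray(covariance, dtype=float) if covariance is not None else (
        aggregate.covariance()
    )
    min_eig = np.linalg.eigvalsh((cov + cov.T) / 2).min()
    if min_eig < -_PSD_TOL:
        if repair_psd:
            cov = nearest_psd(cov)
        else:
            raise CovarianceError(
                f"covariance is not positive semi-definite (min eigenvalue "
                f"{min_eig:.3g}); pass repair_psd=True to apply a nearest-PSD "
                "eigenvalue repair"
            )

    if np.allclose(cov, 0.0):
        # Point mass: every record equals the mean vector.
        if not ranges.contains(mean)[0]:
            raise InfeasibilityError(
                "degenerate aggregate (all SDs zero) with mean outside the "
                "permissible ranges"
            )
        records = np.tile(mean, (n_sim, 1))
        frame = pd.DataFrame(records, columns=list(VARIABLES))
        frame["female"] = 1.0
        frame.attrs["acceptance_rate"] = 1.0
        return frame

    accepted: list[np.ndarray] = []
    n_accepted = 0
    n_drawn = 0
    batch = max(2 * n_sim, 1024)
    while n_accepted < n_sim:
        draws = rng.multivariate_normal(mean, cov, size=batch, method="eigh")
        mask = ranges.contains(draws)
        kept = draws[mask]
        accepted.append(kept)
        n_accepted += len(kept)
        n_drawn += batch
        rate = n_accepted / n_drawn
        if n_drawn >= max_draws and rate < acceptance_floor:
            raise InfeasibilityError(
                f"acceptance rate {rate:.3g} below floor {acceptance_floor:.3g} "
                f"after {n_drawn} draws; the aggregate is incompatible with the "
                "permissible ranges"
            )
        if n_accepted < n_sim:
            # Size the next batch from the running acceptance estimate.
            remaining = n_sim - n_accepted
            batch = int(min(max(remaining / max(rate, 1e-6) * 1.2, 1024), 2_000_000))

    records = np.concatenate(accepted)[:n_sim]
    frame = pd.DataFrame(records, columns=list(VARIABLES))
    frame["female"] = 1.0
    frame.attrs["acceptance_rate"] = n_accepted / n_drawn
    return frame


ARM_CODES = {"active": 1, "placebo": 2}
VISIT_CODES = {"baseline": 1, "endpoint": 2}


def child_seed(
    root_seed: int, study_id: str, arm: str, visit: str
) -> np.random.SeedSequence:
    """Stable per-study/arm/visit RNG stream.

    The stream key is (root, crc32(study_id), arm code, visit code), so adding
    or reordering studies never perturbs the draws of the others.
    """
    return np.random.SeedSequence(
        [int(root_seed), zlib.crc32(study_id.encode()), ARM_CODES[arm], VISIT_CODES[visit]]
    )


@dataclass
class SimulationReport:
    """Per-study/arm/visit diagnostics of a batch simulation run."""

    acceptance_rates: dict = field(default_factory=dict)
    #: max over variables of |sample mean - input mean| / (input SD / sqrt(n)),
    #: i.e. a standardised moment diagnostic (large values flag binding boxes).
    moment_z: dict = field(default_factory=dict)

    def worst_moment_z(self) -> float:
        return max(self.moment_z.values(), default=0.0)


def run_batch(
    studies: Mapping[str, Mapping[str, Mapping[str, ArmAggregate]]],
    n_per_arm: int = 10_000,
    seed: int = 0,
    ranges: PermissibleRanges | None = None,
    **sample_kwargs,
) -> tuple[dict[str, pd.DataFrame], SimulationReport]:
    """Simulate every study/arm/visit of a batch.

    ``studies`` maps study_id -> arm ("active"/"placebo") -> visit
    ("baseline"/"endpoint") -> :class:`ArmAggregate`.  Each cell receives
    ``n_per_arm`` records drawn from its own child stream of ``seed``.
    Returns one long-format DataFrame per study (columns: arm, visit, the
    five clinical variables, female) and a :class:`SimulationReport`.
    """
    ranges = ranges or PermissibleRanges()
    report = SimulationReport()
    out: dict[str, pd.DataFrame] = {}
    for study_id, arms in studies.items():
        pieces = []
        for arm, visits in arms.items():
            for visit, aggregate in visits.items():
                try:
                    frame = sample_ipd(
                        aggregate,
                        n_per_arm,
                        ranges=ranges,
                        seed=child_seed(seed, study_id, arm, visit),
                        **sample_kwargs,
                    )
                except Exception as exc:
                    raise type(exc)(
                        f"study {study_id!r}, arm {arm!r}, visit {visit!r}: {exc}"
                    ) from exc
                key = (study_id, arm, visit)
                report.acceptance_rates[key] = frame.attrs["acceptance_rate"]
                sample_means = frame[list(VARIABLES)].mean().to_numpy()
                se = np.where(
                    aggregate.sds > 0, aggregate.sds / np.sqrt(n_per_arm), np.inf
                )
                report.moment_z[key] = float(
                    np.max(np.abs(sample_means - aggregate.means) / se)
                )
                frame = frame.copy()
                frame.insert(0, "visit", visit)
                frame.insert(0, "arm", arm)
                pieces.append(frame)
        out[study_id] = pd.concat(pieces, ignore_index=True)
        logger.debug(
            "simulated study %s: %d records", study_id, len(out[study_id])
        )
    return out, report
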