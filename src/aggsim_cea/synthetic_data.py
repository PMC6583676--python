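"""Synthetic two-arm trials with known ground truth.

Every downstream stage — pseudo-IPD reconstruction, utility mapping, pooling,
QALY and ICER computation — is testable without any external data because
this module generates complete trials from a fully specified truth:
per-arm/per-visit means, SDs and correlations of the five clinical variables,
a within-patient correlation linking baseline and endpoint (so utility
*changes* have realistic, non-degenerate variance), and a true coefficient
vector for the utility equation.

The default truth emulates a moderate knee-OA population (baseline WOMAC pain
around 10/20, function around 34/68) with a modest treatment effect; all
parameters are overridable.  What the generator deliberately does not emulate:
dropout, measurement floor/ceiling pile-ups, non-normal skew, or site effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InfeasibilityError, ValidationError
from .ipd_simulation import PermissibleRanges
from .study_data import VARIABLES, ArmAggregate, Formulation, StudyResult
from .utility_model import UtilityCoefficients, compute_utility

ARMS = ("active", "placebo")

#: Baseline truth: (pain, function, stiffness, age, years_since_oa).
DEFAULT_BASELINE_MEANS = (10.0, 34.0, 4.0, 62.0, 8.0)
DEFAULT_SDS = (2.5, 9.0, 1.0, 8.0, 2.2)
#: Mean improvement (subtracted from the symptom scales) per arm.  Effects are
#: kept modest so endpoint means stay ~3 SD inside the permissible boxes and
#: truncation is a negligible perturbation (the regime the procedure assumes).
DEFAULT_EFFECT = {"active": (2.0, 7.0, 0.6, 0.0, 0.0), "placebo": (0.8, 2.8, 0.25, 0.0, 0.0)}

DEFAULT_CORR = (
    (1.0, 0.6, 0.5, 0.1, 0.1),
    (0.6, 1.0, 0.5, 0.1, 0.1),
    (0.5, 0.5, 1.0, 0.1, 0.1),
    (0.1, 0.1, 0.1, 1.0, 0.3),
    (0.1, 0.1, 0.1, 0.3, 1.0),
)

#: Synthetic placeholder coefficients (plausible magnitudes, not a published fit).
DEFAULT_COEFFICIENTS = UtilityCoefficients(
    intercept=0.875,
    pain=-0.0165,
    function=-0.0043,
    stiffness=-0.0105,
    age=-0.0005,
    years_since_oa=-0.0013,
    female=-0.0045,
    source="synthetic placeholder",
)


@dataclass(frozen=True)
class TruthSpec:
    """Complete ground truth of one synthetic two-arm, two-visit trial."""

    study_id: str = "synthetic-trial"
    formulation: Formulation = Formulation.OTHER
    #: arm -> visit -> length-5 mean vector
    means: Mapping[str, Mapping[str, tuple]] = None
    #: arm -> visit -> length-5 SD vector
    sds: Mapping[str, Mapping[str, tuple]] = None
    #: arm -> 5x5 correlation (shared by both visits of that arm)
    corr: Mapping[str, tuple] = None
    within_corr: float = 0.6
    n_per_arm: int = 10_000
    duration_months: int = 6
    coefficients: UtilityCoefficients = DEFAULT_COEFFICIENTS
    seed: int = 0

    def __post_init__(self):
        if self.means is None or self.sds is None or self.corr is None:
            raise ValidationError(
                "means, sds and corr are required; use default_truth_spec() for "
                "ready-made defaults"
            )
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2")
        if not -1.0 < self.within_corr < 1.0:
            raise ValidationError("within_corr must be in (-1, 1)")
        for arm in ARMS:
            # ArmAggregate validation covers the structural constraints.
            for visit in ("baseline", "endpoint"):
                ArmAggregate(
                    means=self.means[arm][visit],
                    sds=self.sds[arm][visit],
                    corr=self.corr[arm],
                    n=self.n_per_arm,
                    visit=visit,
                )

    def true_mean_change(self, arm: str) -> float:
        """Analytic mean utility change of the untruncated truth (by linearity)."""
        diff = np.asarray(self.means[arm]["endpoint"], dtype=float) - np.asarray(
            self.means[arm]["baseline"], dtype=float
        )
        return float(self.coefficients.slopes() @ diff)


def default_truth_spec(seed: int = 0, **overrides) -> TruthSpec:
    """The documented moderate-knee-OA default truth (see module docstring)."""
    means = {}
    sds = {}
    corr = {}
    for arm in ARMS:
        base = np.array(DEFAULT_BASELINE_MEANS)
        end = base - np.array(DEFAULT_EFFECT[arm])
        means[arm] = {"baseline": tuple(base), "endpoint": tuple(end)}
        sds[arm] = {"baseline": DEFAULT_SDS, "endpoint": DEFAULT_SDS}
        corr[arm] = DEFAULT_CORR
    kwargs = dict(means=means, sds=sds, corr=corr, seed=seed)
    kwargs.update(overrides)
    return TruthSpec(**kwargs)


def random_truth_spec(seed: int) -> TruthSpec:
    """A randomised truth within realistic interior parameter ranges.

    Baseline means and effects are drawn well inside the permissible boxes so
    that range truncation is a negligible perturbation — the regime the
    pseudo-IPD procedure assumes.  Used for replicate-based validation of the
    whole simulation pathway.
    """
    rng = np.random.default_rng(seed)
    base = np.array(
        [
            rng.uniform(9.0, 12.0),  # pain
            rng.uniform(30.0, 40.0),  # function
            rng.uniform(4.0, 5.0),  # stiffness
            rng.uniform(55.0, 70.0),  # age
            rng.uniform(7.0, 12.0),  # years since OA
        ]
    )
    sds = np.array(
        [
            rng.uniform(1.8, 2.4),
            rng.uniform(6.0, 7.5),
            rng.uniform(0.8, 1.0),
            rng.uniform(6.0, 9.0),
            rng.uniform(1.5, 2.2),
        ]
    )
    means = {}
    sd_map = {}
    corr = {}
    for arm in ARMS:
        scale = 1.0 if arm == "active" else rng.uniform(0.2, 0.6)
        effect = scale * np.array(
            [rng.uniform(1.0, 2.0), rng.uniform(4.0, 8.0), rng.uniform(0.3, 0.8), 0, 0]
        )
        means[arm] = {"baseline": tuple(base), "endpoint": tuple(base - effect)}
        sd_map[arm] = {"baseline": tuple(sds), "endpoint": tuple(sds)}
        corr[arm] = DEFAULT_CORR
    return default_truth_spec(
        seed=int(rng.integers(2**31 - 1)),
        means=means,
        sds=sd_map,
        corr=corr,
        within_corr=float(rng.uniform(0.4, 0.7)),
        study_id=f"synthetic-{seed}",
    )


def _joint_moments(spec: TruthSpec, arm: str):
    """Mean and covariance of the 10-dim (baseline, endpoint) joint normal."""
    mb = np.asarray(spec.means[arm]["baseline"], dtype=float)
    me = np.asarray(spec.means[arm]["endpoint"], dtype=float)
    db = np.diag(spec.sds[arm]["baseline"])
    de = np.diag(spec.sds[arm]["endpoint"])
    c = np.asarray(spec.corr[arm], dtype=float)
    cov = np.block(
        [
            [db @ c @ db, spec.within_corr * db @ c @ de],
            [spec.within_corr * de @ c @ db, de @ c @ de],
        ]
    )
    return np.concatenate([mb, me]), cov


def generate_trial(
    spec: TruthSpec, ranges: PermissibleRanges | None = None
) -> tuple[pd.DataFrame, dict, StudyResult]:
    """Generate one trial: IPD, per-arm/visit aggregates, and its StudyResult.

    IPD is drawn from the box-truncated joint normal implied by the spec
    (both visits of a patient must be in range, otherwise the whole patient
    is redrawn).  Aggregates are computed from the generated records; the
    StudyResult's utility changes are the realized mean changes under the
    true coefficients.  Identical seed, identical output.
    """
    ranges = ranges or PermissibleRanges()
    frames = []
    aggregates: dict[str, dict[str, ArmAggregate]] = {}
    deltas = {}
    for arm_index, arm in enumerate(ARMS):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), arm_index])
        )
        mean, cov = _joint_moments(spec, arm)
        if np.allclose(cov, 0.0):
            in_range = ranges.contains(mean[:5])[0] and ranges.contains(mean[5:])[0]
            if not in_range:
                raise InfeasibilityError(
                    f"{spec.study_id} arm {arm}: degenerate truth outside ranges"
                )
            draws = np.tile(mean, (spec.n_per_arm, 1))
        else:
            kept = []
            n_kept = 0
            n_drawn = 0
            batch = max(2 * spec.n_per_arm, 1024)
            while n_kept < spec.n_per_arm:
                block = rng.multivariate_normal(mean, cov, size=batch, method="eigh")
                mask = ranges.contains(block[:, :5]) & ranges.contains(block[:, 5:])
                kept.append(block[mask])
                n_kept += int(mask.sum())
                n_drawn += batch
                if n_drawn >= 1_000_000 and n_kept / n_drawn < 1e-6:
                    raise InfeasibilityError(
                        f"{spec.study_id} arm {arm}: acceptance probability below "
                        "1e-6; the truth is incompatible with the permissible ranges"
                    )
                batch = int(
                    min(
                        max(
                            (spec.n_per_arm - n_kept)
                            / max(n_kept / n_drawn, 1e-6)
                            * 1.2,
                            1024,
                        ),
                        2_000_000,
                    )
                )
            draws = np.concatenate(kept)[: spec.n_per_arm]

        visit_values = {"baseline": draws[:, :5], "endpoint": draws[:, 5:]}
        aggregates[arm] = {}
        visit_utilities = {}
        for visit, values in visit_values.items():
            frame = pd.DataFrame(values, columns=list(VARIABLES))
            frame["female"] = 1.0
            visit_utilities[visit] = compute_utility(
                frame, spec.coefficients, warn_band=False
            )
            aggregates[arm][visit] = ArmAggregate(
                means=values.mean(axis=0),
                sds=values.std(axis=0, ddof=1),
                corr=_safe_corr(values),
                n=spec.n_per_arm,
                visit=visit,
            )
            frame.insert(0, "visit", visit)
            frame.insert(0, "patient", np.arange(spec.n_per_arm))
            frame.insert(0, "arm", arm)
            frame.insert(0, "study_id", spec.study_id)
            frames.append(frame)
        deltas[arm] = float(
            visit_utilities["endpoint"].mean() - visit_utilities["baseline"].mean()
        )

    ipd = pd.concat(frames, ignore_index=True)
    result = StudyResult(
        study_id=spec.study_id,
        formulation=spec.formulation,
        n=2 * spec.n_per_arm,
        duration_months=spec.duration_months,
        delta_active=deltas["active"],
        delta_placebo=deltas["placebo"],
        n_active=spec.n_per_arm,
        n_placebo=spec.n_per_arm,
    )
    return ipd, aggregates, result


def _safe_corr(values: np.ndarray) -> np.ndarray:
    """Sample correlation with degenerate (zero-variance) columns mapped to 0."""
    sds = values.std(axis=0, ddof=1)
    if np.all(sds > 0):
        corr = np.corrcoef(values, rowvar=False)
        return np.clip((corr + corr.T) / 2, -1.0, 1.0)
    k = values.shape[1]
    corr = np.eye(k)
    live = np.flatnonzero(sds > 0)
    if live.size > 1:
        sub = np.corrcoef(values[:, live], rowvar=False)
        corr[np.ix_(live, live)] = np.clip((sub + sub.T) / 2, -1.0, 1.0)
    return corr
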