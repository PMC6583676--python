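"""Linear WOMAC-to-utility mapping and per-arm change summaries.

Health utility is estimated from the clinical variables by a linear
regression of the Grootendorst type:

    utility = b0 + b_pain*pain + b_function*function + b_stiffness*stiffness
              + b_age*age + b_years*years_since_oa + b_female*female

with ``female`` fixed to 1 for the simulated populations.  The coefficient
values are configuration, not code: the published equation lives in its own
reference, so users transcribe it into a YAML profile.  The bundled
``placeholder`` profile is synthetic (plausible magnitudes only) and exists
so the simulation machinery is testable end-to-end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputError
from .study_data import VARIABLES

logger = logging.getLogger(__name__)

_TERMS = ("intercept",) + VARIABLES + ("female",)

#: Diagnostic plausibility band for utilities of in-range records.
PLAUSIBLE_BAND = (-0.5, 1.0)


@dataclass(frozen=True)
class UtilityCoefficients:
    """Coefficients of the linear utility equation (all required, finite)."""

    intercept: float
    pain: float
    function: float
    stiffness: float
    age: float
    years_since_oa: float
    female: float
    source: str = ""

    def __post_init__(self):
        for term in _TERMS:
            value = getattr(self, term)
            if value is None:
                raise ConfigurationError(f"utility coefficient {term!r} is unset")
            value = float(value)
            if not math.isfinite(value):
                raise ConfigurationError(
                    f"utility coefficient {term!r} must be finite, got {value}"
                )
            object.__setattr__(self, term, value)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "UtilityCoefficients":
        missing = [t for t in _TERMS if t not in mapping]
        if missing:
            raise ConfigurationError(
                f"utility profile is missing coefficient(s): {', '.join(missing)}"
            )
        return cls(**{t: mapping[t] for t in _TERMS}, source=mapping.get("source", ""))

    def slopes(self) -> np.ndarray:
        """Coefficients of the five clinical variables, in canonical order."""
        return np.array([getattr(self, v) for v in VARIABLES])


def load_utility_profile(name_or_path: str | Path = "placeholder") -> UtilityCoefficients:
    """Load a named bundled profile or a user YAML file.

    A path argument must point to a YAML mapping of coefficient names to
    values; a bare name selects a profile from the bundled
    ``data/utility_profiles.yaml``.
    """
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") or path.exists():
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return UtilityCoefficients.from_mapping(doc)
    ref = resources.files("aggsim_cea").joinpath("data", "utility_profiles.yaml")
    with resources.as_file(ref) as p, open(p) as fh:
        profiles = yaml.safe_load(fh)["profiles"]
    if str(name_or_path) not in profiles:
        raise ConfigurationError(
            f"unknown utility profile {name_or_path!r}; bundled profiles: "
            f"{sorted(profiles)}"
        )
    return UtilityCoefficients.from_mapping(profiles[str(name_or_path)])


def compute_utility(
    record,
    coef: UtilityCoefficients,
    clamp: bool = False,
    warn_band: bool = True,
):
    """Utility of one record (mapping/Series) or a column of records (DataFrame).

    ``female`` defaults to 1 when absent.  Utilities are raw regression
    outputs; ``clamp=True`` optionally restricts them to [0, 1].  Values
    outside the plausible band trigger a diagnostic warning, never an error.
    """
    if isinstance(record, pd.DataFrame):
        female = record["female"].to_numpy() if "female" in record else 1.0
        u = (
            coef.intercept
            + record[list(VARIABLES)].to_numpy() @ coef.slopes()
            + coef.female * female
        )
    else:
        female = record.get("female", 1.0) if hasattr(record, "get") else getattr(
            record, "female", 1.0
        )
        get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
        u = coef.intercept + coef.female * float(female)
        for var in VARIABLES:
            u += getattr(coef, var) * float(get(var))
    if warn_band:
        lo, hi = PLAUSIBLE_BAND
        if np.any(np.asarray(u) < lo) or np.any(np.asarray(u) > hi):
            logger.warning(
                "utility outside the plausible band [%s, %s]; check the "
                "coefficient profile and input scales",
                lo,
                hi,
            )
    if clamp:
        u = np.clip(u, 0.0, 1.0)
    if isinstance(record, pd.DataFrame):
        return pd.Series(u, index=record.index, name="utility")
    return float(u)


def summarize_change(
    baseline: pd.DataFrame, endpoint: pd.DataFrame, coef: UtilityCoefficients
) -> float:
    """Mean utility change: mean(endpoint utilities) - mean(baseline utilities).

    By linearity this equals the utility of the mean endpoint record minus the
    utility of the mean baseline record; that identity is used as a fast
    oracle in the test suite.
    """
    if len(baseline) == 0 or len(endpoint) == 0:
        raise InputError("baseline and endpoint collections must be non-empty")
    return float(
        compute_utility(endpoint, coef, warn_band=False).mean()
        - compute_utility(baseline, coef, warn_band=False).mean()
    )
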