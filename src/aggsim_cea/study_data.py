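"""Domain model and I/O for per-study utility-change summaries and arm aggregates.

The central input of the analysis is a small table of published trials, one row
per study: glucosamine formulation class, total number of subjects N, study
duration in months, and the mean health-utility change in each arm.  The
bundled fixture (``load_study_table()``) carries the ten knee-osteoarthritis
glucosamine trials the analysis was built around.

For the simulation pathway, per-arm/per-visit aggregate statistics (means,
SDs, correlations of the WOMAC subscales, age and disease duration) are
modelled by :class:`ArmAggregate`; missing entries can be completed from a
:class:`FallbackTable` with per-field provenance flags.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    CompletenessError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Order of the five clinical variables used throughout the package.
VARIABLES = ("pain", "function", "stiffness", "age", "years_since_oa")

VISITS = ("baseline", "endpoint")

_PSD_TOL = 1e-8


class Formulation(str, enum.Enum):
    """Closed set of formulation classes; unknown strings are rejected."""

    PCGS = "pCGS"
    OTHER = "other_glucosamine"

    @classmethod
    def parse(cls, value: str | "Formulation") -> "Formulation":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unknown formulation {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class StudyResult:
    """One published trial: total N, duration, and per-arm utility change.

    ``n`` is the total number of subjects contributing to the study (the
    published tables print only the total).  The per-arm split is not needed
    for pooling, which weights by total N; optional ``n_active``/``n_placebo``
    overrides are accepted where a user knows the split.
    """

    study_id: str
    formulation: Formulation
    n: int
    duration_months: int
    delta_active: float
    delta_placebo: float
    n_active: int | None = None
    n_placebo: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "formulation", Formulation.parse(self.formulation))
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if int(self.n) < 1:
            raise ValidationError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if int(self.duration_months) < 1:
            raise ValidationError(
                f"{self.study_id}: duration_months must be >= 1, got "
                f"{self.duration_months}"
            )
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "duration_months", int(self.duration_months))
        for arm in ("delta_active", "delta_placebo"):
            v = float(getattr(self, arm))
            if not math.isfinite(v) or not -1.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.study_id}: {arm} must be finite and in [-1, 1], got {v}"
                )
            object.__setattr__(self, arm, v)

    def arm_n(self, arm: str) -> int:
        """Per-arm subject count; equal halves unless overridden."""
        override = {"active": self.n_active, "placebo": self.n_placebo}[arm]
        return int(override) if override is not None else self.n // 2


def _as_corr(matrix, context: str) -> np.ndarray:
    corr = np.asarray(matrix, dtype=float)
    k = len(VARIABLES)
    if corr.shape != (k, k):
        raise ValidationError(f"{context}: correlation matrix must be {k}x{k}")
    if not np.allclose(corr, corr.T, atol=_PSD_TOL):
        raise ValidationError(f"{context}: correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=_PSD_TOL):
        raise ValidationError(f"{context}: correlation diagonal must be 1")
    if np.any(np.abs(corr) > 1.0 + _PSD_TOL):
        raise ValidationError(f"{context}: correlation entries must lie in [-1, 1]")
    if np.linalg.eigvalsh((corr + corr.T) / 2).min() < -_PSD_TOL:
        raise ValidationError(f"{context}: correlation matrix is not PSD")
    return corr


@dataclass(frozen=True)
class ArmAggregate:
    """Aggregate statistics of the five clinical variables for one arm/visit."""

    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    n: int
    visit: str = "baseline"

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        k = len(VARIABLES)
        if means.shape != (k,) or sds.shape != (k,):
            raise ValidationError(f"means and sds must have length {k}")
        if not np.all(np.isfinite(means)) or not np.all(np.isfinite(sds)):
            raise ValidationError("means and sds must be finite")
        if np.any(sds < 0):
            raise ValidationError("sds must be non-negative")
        corr = _as_corr(self.corr, "ArmAggregate")
        if int(self.n) < 1:
            raise ValidationError("n must be >= 1")
        if self.visit not in VISITS:
            raise ValidationError(f"visit must be one of {VISITS}")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "corr", corr)
        object.__setattr__(self, "n", int(self.n))

    def covariance(self) -> np.ndarray:
        d = np.diag(self.sds)
        return d @ self.corr @ d


@dataclass(frozen=True)
class FallbackTable:
    """Default per-variable means/SDs and correlation used to fill gaps.

    The analysis replaces summary statistics that a publication does not
    report (often SDs, or the years-since-diagnosis variable) with values
    from a reference study.  The table bundled with this package
    (``data/fallback_synthetic.yaml``) is a synthetic stand-in with plausible
    moderate-knee-OA magnitudes, since the reference study's raw statistics
    are not published.
    """

    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        k = len(VARIABLES)
        if means.shape != (k,) or sds.shape != (k,):
            raise ValidationError(f"fallback means and sds must have length {k}")
        if np.any(sds < 0):
            raise ValidationError("fallback sds must be non-negative")
        corr = _as_corr(self.corr, "FallbackTable")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "corr", corr)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FallbackTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        means = [doc["means"][v] for v in VARIABLES]
        sds = [doc["sds"][v] for v in VARIABLES]
        return cls(means=means, sds=sds, corr=doc["corr"])


REQUIRED_COLUMNS = (
    "study_id",
    "formulation",
    "n",
    "duration_months",
    "delta_active",
    "delta_placebo",
)
_OPTIONAL_COLUMNS = ("n_active", "n_placebo")
_NUMERIC_COLUMNS = ("n", "duration_months", "delta_active", "delta_placebo")


def read_study_table(
    path: str | Path, format: str | None = None
) -> list[StudyResult]:
    """Read a study-summary table from CSV or JSON.

    The format is inferred from the file suffix unless given explicitly.
    An empty file yields an empty list (with a logged warning); a missing
    required column raises :class:`SchemaError`; a non-numeric cell raises
    :class:`ParseError` carrying the row index.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, dtype={"study_id": str, "formulation": str})
        except pd.errors.EmptyDataError:
            logger.warning("study table %s is empty", path)
            return []
    else:
        text = path.read_text().strip()
        if not text:
            logger.warning("study table %s is empty", path)
            return []
        frame = pd.DataFrame(json.loads(text))
    if frame.empty:
        logger.warning("study table %s has no rows", path)
        return []
    return studies_from_frame(frame)


def studies_from_frame(frame: pd.DataFrame) -> list[StudyResult]:
    """Validate a DataFrame of study rows into :class:`StudyResult` records."""
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    records = []
    for idx, row in frame.iterrows():
        values = {}
        for col in _NUMERIC_COLUMNS:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {row[col]!r} in column {col!r} at row {idx}",
                    row=int(idx),
                ) from None
        extra = {}
        for col in _OPTIONAL_COLUMNS:
            if col in frame.columns and not pd.isna(row[col]):
                extra[col] = int(row[col])
        records.append(
            StudyResult(
                study_id=str(row["study_id"]),
                formulation=Formulation.parse(row["formulation"]),
                n=int(values["n"]),
                duration_months=int(values["duration_months"]),
                delta_active=values["delta_active"],
                delta_placebo=values["delta_placebo"],
                **extra,
            )
        )
    return records


def write_study_table(
    records: Iterable[StudyResult], path: str | Path, format: str | None = None
) -> None:
    """Write records to CSV or JSON; round-trips at full double precision."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for r in records:
        row = {
            "study_id": r.study_id,
            "formulation": r.formulation.value,
            "n": r.n,
            "duration_months": r.duration_months,
            "delta_active": r.delta_active,
            "delta_placebo": r.delta_placebo,
        }
        if r.n_active is not None:
            row["n_active"] = r.n_active
        if r.n_placebo is not None:
            row["n_placebo"] = r.n_placebo
        rows.append(row)
    frame = pd.DataFrame(rows)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(rows, indent=1))


def _data_path(name: str):
    return resources.files("aggsim_cea").joinpath("data", name)


def load_study_table() -> list[StudyResult]:
    """The bundled ten-trial glucosamine study table (four pCGS, six other)."""
    with resources.as_file(_data_path("table1.csv")) as p:
        return read_study_table(p)


def load_price_ranges() -> pd.DataFrame:
    """Bundled per-formulation daily price levels (lowest/median/highest, EUR)."""
    with resources.as_file(_data_path("price_ranges.csv")) as p:
        return pd.read_csv(p)


def load_fallback_table() -> FallbackTable:
    """Bundled synthetic fallback summary table (see class docstring)."""
    with resources.as_file(_data_path("fallback_synthetic.yaml")) as p:
        return FallbackTable.from_yaml(p)


def apply_fallback(
    aggregate: Mapping, fallback: FallbackTable
) -> tuple[ArmAggregate, dict]:
    """Complete a partial aggregate from the fallback table.

    ``aggregate`` is a mapping with keys ``means`` and ``sds`` (mappings from
    variable name to value, where a missing key, ``None`` or NaN marks an
    unavailable statistic), optional ``corr`` (full matrix, entrywise-NaN
    allowed, or ``None``/absent for fully missing), ``n`` and ``visit``.

    Returns the completed :class:`ArmAggregate` and a provenance dict mapping
    ``("means", var)`` / ``("sds", var)`` / ``("corr",)`` to ``"observed"``
    or ``"fallback"``.  Raises :class:`CompletenessError` if a value is
    missing from both sources (the fallback table is fully populated by
    construction, so this triggers only for malformed fallbacks).
    """
    flags: dict = {}

    def fill(kind: str, source: Mapping | None, defaults: np.ndarray) -> np.ndarray:
        out = np.empty(len(VARIABLES))
        source = source or {}
        for i, var in enumerate(VARIABLES):
            value = source.get(var)
            missing = value is None or (
                isinstance(value, float) and math.isnan(value)
            )
            if not missing:
                out[i] = float(value)
                flags[(kind, var)] = "observed"
            else:
                default = defaults[i]
                if default is None or math.isnan(default):
                    raise CompletenessError(
                        f"{kind} for {var!r} missing from both aggregate and fallback"
                    )
                out[i] = default
                flags[(kind, var)] = "fallback"
        return out

    means = fill("means", aggregate.get("means"), fallback.means)
    sds = fill("sds", aggregate.get("sds"), fallback.sds)

    corr_in = aggregate.get("corr")
    if corr_in is None:
        corr = fallback.corr.copy()
        flags[("corr",)] = "fallback"
    else:
        corr = np.asarray(corr_in, dtype=float)
        mask = np.isnan(corr)
        if mask.any():
            corr = np.where(mask, fallback.corr, corr)
            flags[("corr",)] = "fallback"
        else:
            flags[("corr",)] = "observed"

    completed = ArmAggregate(
        means=means,
        sds=sds,
        corr=corr,
        n=int(aggregate.get("n", 1)),
        visit=aggregate.get("visit", "baseline"),
    )
    n_fallback = sum(1 for v in flags.values() if v == "fallback")
    if n_fallback:
        logger.info("apply_fallback: %d field(s) taken from fallback table", n_fallback)
    return completed, flags
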