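import math

import numpy as np
import pytest

from aggsim_cea import (
    ArmAggregate,
    FallbackTable,
    Formulation,
    StudyResult,
    apply_fallback,
    read_study_table,
    write_study_table,
)
from aggsim_cea.exceptions import (
    CompletenessError,
    ParseError,
    SchemaError,
    ValidationError,
)
from aggsim_cea.study_data import VARIABLES, load_fallback_table

# Published per-study values the fixture must carry cell by cell.
EXPECTED_TABLE1 = {
    "giordano": ("pCGS", 60, 3, 0.135, -0.0742),
    "herrero_beaumont": ("pCGS", 210, 6, 0.0785, 0.0315),
    "reginster": ("pCGS", 212, 36, 0.1606, 0.1427),
    "pavelka": ("pCGS", 202, 36, 0.0487, 0.0207),
    "houpt": ("other_glucosamine", 101, 2, 0.0293, 0.0129),
    "mcalindon": ("other_glucosamine", 205, 3, -0.0465, -0.0339),
    "frestedt": ("other_glucosamine", 35, 3, 0.1629, 0.0613),
    "chopra": ("other_glucosamine", 70, 3, 0.0016, 0.1232),
    "cibere": ("other_glucosamine", 137, 6, 0.0096, 0.0006),
    "clegg": ("other_glucosamine", 630, 6, 0.0242, 0.0383),
}


def test_bundled_fixture_matches_published_table(table1):
    assert len(table1) == 10
    assert sum(1 for s in table1 if s.formulation is Formulation.PCGS) == 4
    by_id = {s.study_id: s for s in table1}
    assert set(by_id) == set(EXPECTED_TABLE1)
    for study_id, (form, n, dur, da, dp) in EXPECTED_TABLE1.items():
        s = by_id[study_id]
        assert s.formulation.value == form
        assert s.n == n
        assert s.duration_months == dur
        assert s.delta_active == da
        assert s.delta_placebo == dp


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_round_trip_is_exact(table1, tmp_path, fmt):
    path = tmp_path / f"studies.{fmt}"
    write_study_table(table1, path)
    back = read_study_table(path)
    assert back == table1


def test_empty_file_yields_empty_collection(tmp_path, caplog):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with caplog.at_level("WARNING"):
        assert read_study_table(path) == []
    assert any("empty" in r.message for r in caplog.records)


def test_missing_column_is_a_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("study_id,formulation,n,duration_months,delta_active\na,pCGS,10,3,0.1\n")
    with pytest.raises(SchemaError, match="delta_placebo"):
        read_study_table(path)


def test_non_numeric_cell_reports_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "study_id,formulation,n,duration_months,delta_active,delta_placebo\n"
        "a,pCGS,10,3,0.1,0.05\n"
        "b,pCGS,10,three,0.1,0.05\n"
    )
    with pytest.raises(ParseError) as exc:
        read_study_table(path)
    assert exc.value.row == 1


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n=0),
        dict(duration_months=0),
        dict(delta_active=1.5),
        dict(delta_placebo=float("nan")),
    ],
)
def test_study_result_invariants(kwargs):
    base = dict(
        study_id="x",
        formulation="pCGS",
        n=10,
        duration_months=3,
        delta_active=0.1,
        delta_placebo=0.0,
    )
    base.update(kwargs)
    with pytest.raises(ValidationError):
        StudyResult(**base)


def test_unknown_formulation_rejected():
    with pytest.raises(ValidationError, match="unknown formulation"):
        StudyResult(
            study_id="x",
            formulation="glucosamine_hcl_extra",
            n=10,
            duration_months=3,
            delta_active=0.1,
            delta_placebo=0.0,
        )


def test_arm_n_defaults_to_equal_halves():
    s = StudyResult("x", "pCGS", 101, 3, 0.1, 0.0)
    assert s.arm_n("active") == 50
    s2 = StudyResult("x", "pCGS", 101, 3, 0.1, 0.0, n_active=60, n_placebo=41)
    assert (s2.arm_n("active"), s2.arm_n("placebo")) == (60, 41)


@pytest.mark.parametrize(
    "corrupt",
    [
        lambda c: c.__setitem__((0, 1), 0.9),  # asymmetric
        lambda c: np.fill_diagonal(c, 0.9),  # diagonal != 1
    ],
)
def test_aggregate_correlation_invariants(corrupt):
    corr = np.eye(5)
    corrupt(corr)
    with pytest.raises(ValidationError):
        ArmAggregate(means=np.zeros(5), sds=np.ones(5), corr=corr, n=10)


def test_aggregate_rejects_negative_sd():
    with pytest.raises(ValidationError, match="non-negative"):
        ArmAggregate(means=np.zeros(5), sds=[-1, 1, 1, 1, 1], corr=np.eye(5), n=10)


class TestApplyFallback:
    def test_missing_sd_filled_and_flagged(self):
        fallback = load_fallback_table()
        partial = {
            "means": {v: 1.0 for v in VARIABLES},
            "sds": {v: 2.0 for v in VARIABLES if v != "years_since_oa"},
            "corr": np.eye(5),
            "n": 50,
            "visit": "baseline",
        }
        completed, flags = apply_fallback(partial, fallback)
        assert completed.sds[VARIABLES.index("years_since_oa")] == pytest.approx(
            fallback.sds[VARIABLES.index("years_since_oa")]
        )
        assert flags[("sds", "years_since_oa")] == "fallback"
        assert flags[("sds", "pain")] == "observed"

    def test_fully_specified_returns_unchanged_with_zero_flags(self):
        fallback = load_fallback_table()
        partial = {
            "means": {v: float(i + 1) for i, v in enumerate(VARIABLES)},
            "sds": {v: 1.0 for v in VARIABLES},
            "corr": np.eye(5),
            "n": 7,
            "visit": "endpoint",
        }
        completed, flags = apply_fallback(partial, fallback)
        np.testing.assert_array_equal(completed.means, np.arange(1.0, 6.0))
        np.testing.assert_array_equal(completed.corr, np.eye(5))
        assert all(v == "observed" for v in flags.values())

    def test_missing_from_both_sources_is_a_completeness_error(self):
        fallback = load_fallback_table()
        broken = FallbackTable(
            means=np.array([math.nan, 30, 4, 60, 5]),
            sds=fallback.sds,
            corr=fallback.corr,
        )
        partial = {"means": {}, "sds": {v: 1.0 for v in VARIABLES}}
        with pytest.raises(CompletenessError, match="pain"):
            apply_fallback(partial, broken)

    def test_missing_correlation_comes_from_fallback(self):
        fallback = load_fallback_table()
        partial = {
            "means": {v: 5.0 for v in VARIABLES},
            "sds": {v: 1.0 for v in VARIABLES},
        }
        completed, flags = apply_fallback(partial, fallback)
        np.testing.assert_array_equal(completed.corr, fallback.corr)
        assert flags[("corr",)] == "fallback"
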