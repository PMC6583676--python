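import numpy as np
import pandas as pd
import pytest

from aggsim_cea import ArmAggregate, PermissibleRanges, run_batch, sample_ipd
from aggsim_cea.exceptions import CovarianceError, InfeasibilityError
from aggsim_cea.ipd_simulation import child_seed, nearest_psd
from aggsim_cea.study_data import VARIABLES


def aggregate(means, sds, corr=None, n=100, visit="baseline"):
    return ArmAggregate(
        means=means, sds=sds, corr=np.eye(5) if corr is None else corr, n=n, visit=visit
    )


def truncated_mean_1d(mean, sd, low, high, rng, n=1_000_000):
    """Brute-force 1-D rejection oracle for the truncated-normal mean."""
    draws = rng.normal(mean, sd, size=n)
    kept = draws[(draws >= low) & (draws <= high)]
    return kept.mean(), kept.std(ddof=1), len(kept)


def test_point_mass_when_all_sds_zero():
    agg = aggregate([10, 30, 4, 60, 5], np.zeros(5))
    frame = sample_ipd(agg, 5, seed=1)
    assert len(frame) == 5
    np.testing.assert_array_equal(
        frame[list(VARIABLES)].to_numpy(), np.tile([10, 30, 4, 60, 5], (5, 1))
    )
    assert (frame["female"] == 1.0).all()


def test_determinism_and_seed_sensitivity():
    agg = aggregate([10, 30, 4, 60, 5], [3, 10, 2, 8, 4])
    a = sample_ipd(agg, 500, seed=42)
    b = sample_ipd(agg, 500, seed=42)
    c = sample_ipd(agg, 500, seed=43)
    pd.testing.assert_frame_equal(a, b)
    assert not a[list(VARIABLES)].equals(c[list(VARIABLES)])


def test_marginal_means_match_1d_rejection_oracle(rng):
    """With identity correlation, each accepted marginal is the 1-D truncated
    normal; sample means must agree with a brute-force oracle within 3 SE."""
    means, sds = [10, 30, 4, 60, 5], [3, 10, 2, 8, 4]
    frame = sample_ipd(aggregate(means, sds), 100_000, seed=7)
    ranges = PermissibleRanges()
    for i, var in enumerate(VARIABLES):
        om, osd, on = truncated_mean_1d(
            means[i], sds[i], ranges.lower[i], ranges.upper[i], rng
        )
        se = osd * np.sqrt(1 / len(frame) + 1 / on)
        assert abs(frame[var].mean() - om) < 3 * se, var


def test_upper_truncation_pulls_mean_inward():
    agg = aggregate([19, 30, 4, 60, 5], [5, 1, 1, 1, 1])
    frame = sample_ipd(agg, 20_000, seed=3)
    assert (frame["pain"] <= 20).all()
    assert frame["pain"].mean() < 19


def test_all_outputs_respect_permissible_ranges():
    agg = aggregate([18, 60, 7, 85, 2], [4, 10, 2, 12, 3])
    frame = sample_ipd(agg, 5_000, seed=11)
    ranges = PermissibleRanges()
    assert ranges.contains(frame[list(VARIABLES)].to_numpy()).all()


def test_parameter_recovery_with_unbounded_ranges():
    """With the boxes removed, sample moments converge to the input aggregate."""
    corr = np.full((5, 5), 0.3) + 0.7 * np.eye(5)
    means, sds = np.array([10.0, 30, 4, 60, 5]), np.array([3.0, 10, 2, 8, 4])
    agg = aggregate(means, sds, corr=corr)
    n = 100_000
    frame = sample_ipd(agg, n, ranges=PermissibleRanges().widened(np.inf), seed=5)
    values = frame[list(VARIABLES)].to_numpy()
    assert np.all(np.abs(values.mean(axis=0) - means) < 3 * sds / np.sqrt(n))
    np.testing.assert_allclose(values.std(axis=0, ddof=1), sds, rtol=0.02)
    sample_corr = np.corrcoef(values, rowvar=False)
    np.testing.assert_allclose(sample_corr, corr, atol=3.5 / np.sqrt(n) + 0.005)


def test_widening_a_range_never_lowers_acceptance():
    # Single-batch regime so both runs see the same underlying draws.
    agg = aggregate([18, 60, 7, 60, 5], [4, 10, 2, 8, 4])
    narrow = PermissibleRanges()
    wide = PermissibleRanges(narrow.lower, narrow.upper + np.array([5, 20, 4, 50, 50]))
    a = sample_ipd(agg, 100, ranges=narrow, seed=9).attrs["acceptance_rate"]
    b = sample_ipd(agg, 100, ranges=wide, seed=9).attrs["acceptance_rate"]
    assert b >= a


def test_non_psd_covariance_suggests_repair():
    # A published "covariance" can fail PSD; passed via the direct-covariance
    # switch it must be rejected with a pointer to the repair flag.
    cov = np.diag([9.0, 100.0, 4.0, 64.0, 16.0])
    cov[0, 1] = cov[1, 0] = 28.0
    cov[0, 2] = cov[2, 0] = 5.8
    cov[1, 2] = cov[2, 1] = -19.0  # impossible triple
    agg = aggregate([10, 30, 4, 60, 5], [3, 10, 2, 8, 4])
    with pytest.raises(CovarianceError, match="repair_psd"):
        sample_ipd(agg, 10, seed=1, covariance=cov)
    frame = sample_ipd(agg, 10, seed=1, covariance=cov, repair_psd=True)
    assert len(frame) == 10


def test_infeasible_aggregate_raises():
    agg = aggregate([50, 30, 4, 60, 5], [0.5, 1, 1, 1, 1])  # pain mean far out of range
    with pytest.raises(InfeasibilityError, match="acceptance rate"):
        sample_ipd(agg, 100, seed=1, max_draws=50_000)


def test_degenerate_point_mass_outside_ranges_is_infeasible():
    agg = aggregate([50, 30, 4, 60, 5], np.zeros(5))
    with pytest.raises(InfeasibilityError):
        sample_ipd(agg, 10, seed=1)


class TestRunBatch:
    def studies(self, ids=("s1", "s2")):
        agg = lambda visit: aggregate([10, 30, 4, 60, 5], [3, 10, 2, 8, 4], visit=visit)
        return {
            sid: {
                arm: {v: agg(v) for v in ("baseline", "endpoint")}
                for arm in ("active", "placebo")
            }
            for sid in ids
        }

    def test_shapes_and_determinism(self):
        ipd, report = run_batch(self.studies(), n_per_arm=10, seed=123)
        assert set(ipd) == {"s1", "s2"}
        for frame in ipd.values():
            assert len(frame) == 10 * 2 * 2  # n x arms x visits
        ipd2, _ = run_batch(self.studies(), n_per_arm=10, seed=123)
        assert ipd["s1"].to_csv() == ipd2["s1"].to_csv()
        assert report.acceptance_rates[("s1", "active", "baseline")] > 0

    def test_adding_a_study_does_not_perturb_others(self):
        ipd_two, _ = run_batch(self.studies(("s1", "s2")), n_per_arm=10, seed=123)
        ipd_three, _ = run_batch(self.studies(("s1", "s2", "s3")), n_per_arm=10, seed=123)
        assert ipd_two["s1"].to_csv() == ipd_three["s1"].to_csv()
        assert ipd_two["s2"].to_csv() == ipd_three["s2"].to_csv()

    def test_error_carries_study_context(self):
        studies = self.studies(("bad",))
        studies["bad"]["active"]["baseline"] = aggregate(
            [50, 30, 4, 60, 5], [0.5, 1, 1, 1, 1]
        )
        with pytest.raises(InfeasibilityError, match="bad"):
            run_batch(studies, n_per_arm=10, seed=1, max_draws=50_000)


def test_child_seed_streams_are_distinct():
    keys = {
        child_seed(1, s, a, v).generate_state(4).tobytes()
        for s in ("s1", "s2")
        for a in ("active", "placebo")
        for v in ("baseline", "endpoint")
    }
    assert len(keys) == 8


def test_nearest_psd_repairs_to_psd():
    m = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
    repaired = nearest_psd(m)
    assert np.linalg.eigvalsh(repaired).min() >= 0
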