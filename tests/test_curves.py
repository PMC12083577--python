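"""Diurnal curve summaries against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import movereserve as mr
from movereserve.curves import METRICS, bin_summary

from conftest import constant_matrix


# -- independent brute-force oracle (explicit sorts / enumeration) ----------

def oracle(pool, metric, cv_threshold=0.0):
    pool = sorted(float(x) for x in pool)
    n = len(pool)
    mean = sum(pool) / n

    def med(xs):
        xs = sorted(xs)
        m = len(xs)
        return xs[m // 2] if m % 2 else 0.5 * (xs[m // 2 - 1] + xs[m // 2])

    if metric == "mean":
        return mean
    if metric == "sd":
        return (sum((x - mean) ** 2 for x in pool) / n) ** 0.5
    if metric == "mad":
        m0 = med(pool)
        return med([abs(x - m0) for x in pool])
    if metric == "cv":
        sd = oracle(pool, "sd")
        return 0.0 if (mean <= cv_threshold or sd <= cv_threshold) else sd / mean
    if metric == "mode":
        counts = {}
        for x in pool:
            counts[x] = counts.get(x, 0) + 1
        best = max(counts.values())
        return min(x for x, c in counts.items() if c == best)
    q = {"q50": 0.50, "q90": 0.90, "q95": 0.95, "q99": 0.99, "q100": 1.00}[metric]
    # inverse empirical CDF (lower order statistic)
    idx = int(np.ceil(q * n)) - 1 if q > 0 else 0
    return pool[max(idx, 0)]


class TestBinSummary:
    def test_order_statistics_of_small_pool(self):
        pool = [1, 2, 3, 4, 5]
        assert bin_summary(pool, "mean") == 3
        assert bin_summary(pool, "q50") == 3
        assert bin_summary(pool, "q100") == 5
        assert bin_summary(pool, "mad") == 1        # deviations {2,1,0,1,2}

    def test_all_zero_pool_cv_zero_rule(self):
        pool = np.zeros(20)
        assert bin_summary(pool, "mean") == 0
        assert bin_summary(pool, "sd") == 0
        assert bin_summary(pool, "cv") == 0

    def test_constant_pool_degenerate_summaries(self):
        pool = [5, 5, 5]
        for metric in METRICS:
            expected = 0.0 if metric in ("sd", "mad", "cv") else 5.0
            assert bin_summary(pool, metric) == expected

    def test_empty_pool_is_missing_not_zero(self):
        assert np.isnan(bin_summary([], "mean"))
        assert np.isnan(bin_summary([np.nan], "q100"))

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_brute_force_oracle(self, metric, rng):
        for _ in range(200):
            pool = rng.integers(0, 500, size=rng.integers(1, 51))
            assert bin_summary(pool, metric) == pytest.approx(
                oracle(pool, metric), abs=1e-12)

    def test_sample_sd_option(self):
        pool = [1.0, 2.0, 3.0]
        assert bin_summary(pool, "sd", sd_denominator="sample") == \
            pytest.approx(1.0)

    def test_cv_threshold_option(self):
        pool = [1.0, 1.0, 4.0]  # mean 2, sd ~1.41
        assert bin_summary(pool, "cv", cv_threshold=2.5) == 0.0
        assert bin_summary(pool, "cv") > 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=40),
           st.floats(0.1, 100.0))
    def test_scale_equivariance(self, pool, k):
        for metric in ("mean", "sd", "mad", "q50", "q90", "q100"):
            a = bin_summary(pool, metric)
            b = bin_summary([k * x for x in pool], metric)
            assert b == pytest.approx(k * a, rel=1e-9)
        assert bin_summary([k * x for x in pool], "cv") == pytest.approx(
            bin_summary(pool, "cv"), rel=1e-9)


class TestPoolBin:
    def test_full_wear_pool_size(self):
        m = constant_matrix(3.0, n_days=3)
        pool = mr.pool_bin(m, mr.BinGrid(), 7)
        assert pool.size == 30  # 3 days x 10 minutes

    def test_nonwear_day_reduces_pool(self):
        m = constant_matrix(3.0, n_days=3)
        m.wear_mask[1, 70:80] = False
        assert mr.pool_bin(m, mr.BinGrid(), 7).size == 20

    def test_pool_equals_brute_force_concatenation(self, rng):
        counts = rng.integers(0, 100, size=(4, 1440)).astype(float)
        m = mr.SubjectDayMatrix("A", list("abcd"), counts)
        m.wear_mask = rng.random((4, 1440)) > 0.2
        g = mr.BinGrid()
        for s in (0, 55, 143):
            brute = np.concatenate(
                [counts[d, s * 10:(s + 1) * 10][m.wear_mask[d, s * 10:(s + 1) * 10]]
                 for d in range(4)])
            assert sorted(mr.pool_bin(m, g, s)) == sorted(brute)


class TestComputeCurve:
    def test_constant_cohort_flat_mean_curve(self):
        c = mr.compute_curve(constant_matrix(7.0), mr.BinGrid(), "mean")
        assert c.values.shape == (144,)
        assert np.allclose(c.values, 7.0)

    def test_q100_matches_pointwise_max_oracle(self, rng):
        counts = rng.integers(0, 800, size=(5, 1440)).astype(float)
        m = mr.SubjectDayMatrix("A", list("abcde"), counts)
        g = mr.BinGrid()
        c = mr.compute_curve(m, g, "q100")
        brute = [mr.pool_bin(m, g, s).max() for s in range(144)]
        assert np.array_equal(c.values, brute)

    def test_quantile_curves_monotone_in_level(self, small_cohort):
        g = mr.BinGrid()
        for m in small_cohort["clean"][:3]:
            cs = mr.compute_curves(m, g, ("q50", "q90", "q95", "q99", "q100"))
            stack = np.vstack([cs[k].values for k in
                               ("q50", "q90", "q95", "q99", "q100")])
            assert np.all(np.diff(stack, axis=0) >= -1e-12)

    def test_sd_zero_iff_constant_pool_iff_mad_zero(self, small_cohort):
        g = mr.BinGrid()
        m = small_cohort["clean"][0]
        cs = mr.compute_curves(m, g, ("sd", "mad", "q100", "q50"))
        ok = ~cs["sd"].imputed_bins
        sd0 = cs["sd"].values[ok] < 1e-12
        mad0 = cs["mad"].values[ok] < 1e-12
        # sd = 0 => constant pool => mad = 0 and all quantiles collapse
        assert np.all(mad0[sd0])
        collapsed = (cs["q100"].values == cs["q50"].values)[ok]
        assert np.all(collapsed[sd0])

    def test_mean_between_min_and_max(self, small_cohort):
        g = mr.BinGrid()
        m = small_cohort["clean"][1]
        cs = mr.compute_curves(m, g, ("mean", "q100"))
        ok = ~cs["mean"].imputed_bins
        assert np.all(cs["mean"].values[ok] <= cs["q100"].values[ok] + 1e-12)

    def test_empty_bin_circular_interpolation(self):
        m = constant_matrix(4.0, n_days=2)
        m.wear_mask[:, 0:10] = False          # bin 0 empty on both days
        c = mr.compute_curve(m, mr.BinGrid(), "mean")
        assert c.imputed_bins[0] and not c.imputed_bins[1]
        assert c.values[0] == pytest.approx(4.0)  # neighbours are both 4

    def test_mostly_empty_subject_flagged_invalid(self):
        m = constant_matrix(4.0, n_days=2)
        m.wear_mask[:, :800] = False           # 80 of 144 bins empty
        c = mr.compute_curve(m, mr.BinGrid(), "mean")
        assert not c.valid and "empty bins" in c.reason


class TestMonotoneTransformCommutation:
    def test_lac_q100_equals_log_of_ac_q100(self, small_cohort):
        g = mr.BinGrid()
        cov = small_cohort["covariates"]
        ac, ids = mr.curve_matrix(small_cohort["clean"], cov, g, "q100", "AC")
        lac, ids2 = mr.curve_matrix(small_cohort["clean"], cov, g, "q100", "LAC")
        assert ids == ids2
        assert np.allclose(lac, np.log1p(ac), atol=1e-12)

    def test_mode_commutes_with_log_transform(self, rng):
        counts = rng.integers(0, 50, size=(3, 1440)).astype(float)
        m = mr.SubjectDayMatrix("A", list("abc"), counts)
        g = mr.BinGrid()
        ac = mr.compute_curve(m, g, "mode").values
        lac = mr.compute_curve(mr.log_transform(m), g, "mode").values
        assert np.allclose(lac, np.log1p(ac), atol=1e-12)

    def test_q50_commutes_on_odd_pools(self, rng):
        counts = rng.integers(0, 50, size=(3, 1440)).astype(float)
        m = mr.SubjectDayMatrix("A", list("abc"), counts)
        g = mr.BinGrid()  # pools of 30 -> even; use inverted_cdf: observed value
        ac = mr.compute_curve(m, g, "q50").values
        lac = mr.compute_curve(mr.log_transform(m), g, "q50").values
        assert np.allclose(lac, np.log1p(ac), atol=1e-12)


class TestCurveMatrix:
    def test_shape_and_row_consistency(self, small_cohort):
        g = mr.BinGrid()
        cov = small_cohort["covariates"]
        mat, ids = mr.curve_matrix(small_cohort["clean"], cov, g, "mean")
        assert mat.shape == (len(ids), 144)
        i = ids.index(small_cohort["clean"][2].subject_id)
        direct = mr.compute_curve(small_cohort["clean"][2], g, "mean")
        assert np.array_equal(mat[i], direct.values)

    def test_row_order_follows_covariate_table(self, small_cohort):
        g = mr.BinGrid()
        cov = small_cohort["covariates"].iloc[::-1].reset_index(drop=True)
        mat, ids = mr.curve_matrix(small_cohort["clean"], cov, g, "mean")
        assert ids == list(cov["subject_id"])

    def test_orphan_curve_subject_raises_join_error(self, small_cohort):
        g = mr.BinGrid()
        cov = small_cohort["covariates"].iloc[:-1]
        with pytest.raises(mr.JoinError, match="missing from covariates"):
            mr.curve_matrix(small_cohort["clean"], cov, g, "mean")


class TestBinGrid:
    def test_default_partition(self):
        g = mr.BinGrid()
        assert g.n_bins == 144
        mids = g.midpoints_hours
        assert np.all(np.diff(mids) > 0)
        assert 0 < mids[0] and mids[-1] < 24

    def test_non_divisor_width_rejected(self):
        with pytest.raises(mr.DimensionError):
            mr.BinGrid(bin_width_minutes=7)
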