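import math

import numpy as np
import pytest
from sklearn import metrics as skm

from uopval import (
    AnalysisConfig,
    CohortSpec,
    PipelineError,
    compute_metrics,
    detect_outliers,
    report_to_json,
    run_validation,
    sample_cohort,
    split_subgroups,
    subsample_cis,
)

METRIC_NAMES = ("mae", "medae", "mse", "rmse", "r2")


class TestComputeMetrics:
    def test_hand_computed_example(self):
        ms = compute_metrics([1, 2, 3], [2, 2, 2])
        assert ms.mae == pytest.approx(2 / 3)
        assert ms.medae == pytest.approx(1.0)
        assert ms.mse == pytest.approx(2 / 3)
        assert ms.rmse == pytest.approx(math.sqrt(2 / 3))
        assert ms.r2 == pytest.approx(0.0, abs=1e-15)

    def test_perfect_fit(self):
        ms = compute_metrics([0.5, 1.5, 2.5], [0.5, 1.5, 2.5])
        assert (ms.mae, ms.medae, ms.mse, ms.rmse) == (0, 0, 0, 0)
        assert ms.r2 == 1.0

    def test_two_point_example(self):
        ms = compute_metrics([0, 2], [1, 1])
        assert ms.mae == 1.0
        assert ms.r2 == pytest.approx(0.0, abs=1e-15)

    def test_even_length_medae_is_midpoint(self):
        ms = compute_metrics([0, 0, 0, 0], [1, 2, 3, 4])
        assert ms.medae == pytest.approx(2.5)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError, match="equal length"):
            compute_metrics([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 2"):
            compute_metrics([1.0], [1.0])

    def test_constant_observed_r2_undefined(self):
        ms = compute_metrics([2, 2, 2], [1, 2, 3])
        assert math.isnan(ms.r2)
        assert ms.mae == pytest.approx(2 / 3)

    def test_matches_sklearn_on_random_pairs(self):
        """Independent textbook implementation agrees to 1e-10 relative."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            observed = rng.normal(2.5, 1.0, n)
            predicted = observed + rng.normal(0, 0.8, n)
            ms = compute_metrics(observed, predicted)
            assert ms.mae == pytest.approx(
                skm.mean_absolute_error(observed, predicted), rel=1e-10)
            assert ms.medae == pytest.approx(
                skm.median_absolute_error(observed, predicted), rel=1e-10)
            assert ms.mse == pytest.approx(
                skm.mean_squared_error(observed, predicted), rel=1e-10)
            assert ms.r2 == pytest.approx(
                skm.r2_score(observed, predicted), rel=1e-10, abs=1e-10)
            assert ms.rmse ** 2 == pytest.approx(ms.mse, rel=1e-12)


class TestSubsampleCis:
    def test_perfect_fit_degenerate_intervals(self):
        v = np.arange(20, dtype=float)
        cis = subsample_cis(v, v, fraction=0.5, iterations=10, seed=0)
        assert (cis["mae"].lo, cis["mae"].hi) == (0.0, 0.0)
        assert (cis["r2"].lo, cis["r2"].hi) == (1.0, 1.0)
        for name in METRIC_NAMES:
            assert cis[name].n_iterations == 10
            assert cis[name].fraction == 0.5

    def test_full_fraction_degenerate(self):
        rng = np.random.default_rng(5)
        o = rng.normal(2.5, 1, 30)
        p = o + rng.normal(0, 0.5, 30)
        cis = subsample_cis(o, p, fraction=1.0, iterations=7, seed=1)
        full = compute_metrics(o, p)
        for name in METRIC_NAMES:
            assert cis[name].lo == pytest.approx(getattr(full, name), rel=1e-12)
            assert cis[name].hi == pytest.approx(getattr(full, name), rel=1e-12)
            assert cis[name].point == pytest.approx(getattr(full, name))

    def test_matches_reference_recomputation(self):
        """Endpoints match an independent re-implementation sharing the
        documented index-drawing procedure (default_rng(seed).choice per
        iteration, without replacement, then interpolated percentiles)."""
        rng = np.random.default_rng(99)
        o = rng.normal(2.5, 1.0, 20)
        p = o + rng.normal(0, 0.7, 20)
        seed, iterations, fraction = 17, 10, 0.5
        cis = subsample_cis(o, p, fraction=fraction, iterations=iterations,
                            seed=seed)
        ref_rng = np.random.default_rng(seed)
        m = math.floor(fraction * o.size)
        maes = []
        for _ in range(iterations):
            idx = ref_rng.choice(o.size, size=m, replace=False)
            maes.append(float(np.mean(np.abs(o[idx] - p[idx]))))
        lo, hi = np.percentile(maes, [2.5, 97.5])
        assert cis["mae"].lo == pytest.approx(lo, rel=1e-12)
        assert cis["mae"].hi == pytest.approx(hi, rel=1e-12)

    def test_interval_ordering_and_point_from_full_sample(self):
        rng = np.random.default_rng(2)
        o = rng.normal(2.5, 1, 40)
        p = o + rng.normal(0, 1, 40)
        full = compute_metrics(o, p)
        for method in ("percentile", "normal"):
            cis = subsample_cis(o, p, seed=3, method=method)
            for name in METRIC_NAMES:
                assert cis[name].lo <= cis[name].hi
                assert cis[name].point == pytest.approx(getattr(full, name))

    def test_too_small_subsample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            subsample_cis([1, 2, 3], [1, 2, 3], fraction=0.5, iterations=10)


class TestDetectOutliers:
    def test_zero_iqr_flags_only_extreme(self):
        mask = detect_outliers([2, 2, 2, 2, 10])
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector_no_outliers(self):
        assert not detect_outliers([3.0] * 6).any()

    def test_small_vector_interpolated_quartiles(self):
        # q1=1.75, q3=3.25, fences [-0.5, 5.5] under the p*(n-1) convention
        assert not detect_outliers([1, 2, 3, 4]).any()

    def test_requires_four_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            detect_outliers([1, 2, 3])

    def test_matches_brute_force_on_random_vectors(self):
        """500 random small vectors against an independently coded Tukey rule
        (manual order-statistic interpolation, no numpy.percentile)."""

        def brute(vals):
            s = sorted(vals)
            n = len(s)

            def quantile(p):
                pos = p * (n - 1)
                lo = math.floor(pos)
                hi = math.ceil(pos)
                return s[lo] + (pos - lo) * (s[hi] - s[lo])

            q1, q3 = quantile(0.25), quantile(0.75)
            iqr = q3 - q1
            return [v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr for v in vals]

        rng = np.random.default_rng(77)
        for k in range(500):
            n = int(rng.integers(4, 25))
            if k % 5 == 0:  # exercise the zero-IQR case
                v = np.repeat(rng.normal(), n)
                v[rng.integers(n)] += rng.normal() * 10
            else:
                v = rng.normal(0, rng.uniform(0.5, 3), n)
            assert detect_outliers(v).tolist() == brute(v.tolist())

    def test_invariance_under_shift_permutation_and_scale(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 30)
        v[:2] += 8  # plant outliers
        base = detect_outliers(v)
        assert (detect_outliers(v + 17.3) == base).all()
        perm = rng.permutation(30)
        assert (detect_outliers(v[perm]) == base[perm]).all()
        assert (detect_outliers(v * 4.2) == base).all()


class TestSplitSubgroups:
    def test_age_boundary_goes_to_older_group(self, make_encounter):
        rows = [make_encounter(age_days=a) for a in (100, 365, 400)]
        groups = split_subgroups(rows)
        assert groups["age_lt_12mo"].tolist() == [0]
        assert groups["age_ge_12mo"].tolist() == [1, 2]

    def test_stat_partition(self, make_encounter):
        rows = [make_encounter(stat_category=c) for c in (1, 2, 3, 4, 5)]
        groups = split_subgroups(rows)
        assert groups["stat_lt_3"].tolist() == [0, 1]
        assert groups["stat_ge_3"].tolist() == [2, 3, 4]

    def test_partitions_cover_cohort(self):
        cohort = sample_cohort(CohortSpec(n_encounters=300, seed=4))
        groups = split_subgroups(cohort)
        n = len(cohort)
        assert len(groups["age_lt_12mo"]) + len(groups["age_ge_12mo"]) == n
        assert len(groups["stat_lt_3"]) + len(groups["stat_ge_3"]) == n

    def test_missing_age_named_in_error(self, make_encounter):
        bad = make_encounter(age_days=float("nan"))
        with pytest.raises(ValueError, match=bad.encounter_id):
            split_subgroups([bad])


class TestRunValidation:
    def test_subgroup_sizes_sum_to_overall(self):
        cohort = sample_cohort(CohortSpec(n_encounters=213, seed=0))
        report = run_validation(cohort)
        n = report.overall.n
        assert (report.subgroups["age_lt_12mo"].n
                + report.subgroups["age_ge_12mo"].n) == n
        assert (report.subgroups["stat_lt_3"].n
                + report.subgroups["stat_ge_3"].n) == n
        assert n == report.exclusion_tally.n_retained

    def test_perfect_fit_cohort(self, make_encounter):
        import dataclasses

        from uopval import predict_rate

        rows = []
        for weight in (3.0, 5.0, 8.0, 12.0, 20.0, 30.0):
            enc = make_encounter(weight_kg=weight, age_days=100 * weight)
            rows.append(dataclasses.replace(
                enc, observed_uop_ml_kg_hr=predict_rate(enc.covariates)))
        report = run_validation(
            rows, AnalysisConfig(outlier_on="residuals"))
        assert report.overall.metrics.mae == 0.0
        assert report.overall.metrics.r2 == 1.0
        assert report.overall.intervals["r2"].lo == 1.0
        assert report.overall.intervals["r2"].hi == 1.0
        assert not report.outlier_mask.any()

    def test_fixed_seed_reproducible(self):
        cohort = sample_cohort(CohortSpec(n_encounters=213, seed=9))
        a = report_to_json(run_validation(cohort, AnalysisConfig(seed=5)))
        b = report_to_json(run_validation(cohort, AnalysisConfig(seed=5)))
        assert a == b

    def test_empty_retained_cohort_raises(self, make_encounter):
        rows = [make_encounter(flags={"ecmo_32h": True}) for _ in range(3)]
        with pytest.raises(PipelineError, match="empty cohort"):
            run_validation(rows)

    def test_outliers_flagged_on_observed_by_default(self, make_encounter):
        rows = [make_encounter(observed=2.5) for _ in range(10)]
        rows.append(make_encounter(observed=50.0))
        report = run_validation(rows)
        assert report.outlier_mask.sum() == 1
        assert report.outlier_mask[-1]
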