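import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrfkit.matching import ParameterMap
from mrfkit.qa import (
    MeasurementTable,
    ROISpec,
    age_trend,
    bland_altman,
    coefficient_of_variation,
    extract_roi_mean,
    percent_deviation,
    qa_report,
    region_summary,
)
from mrfkit.qa import test_retest_variation as retest_variation


def make_map(t1, t2=None, mask=None):
    t1 = np.asarray(t1, dtype=float)
    if t2 is None:
        t2 = np.full_like(t1, 50.0)
    if mask is None:
        mask = np.ones(t1.shape, dtype=bool)
    return ParameterMap(
        t1_ms=t1,
        t2_ms=np.asarray(t2, dtype=float),
        m0_magnitude=np.ones(t1.shape),
        score=np.ones(t1.shape),
        mask=mask,
    )


class TestExtractROIMean:
    def test_uniform_map(self):
        pmap = make_map(np.full((40, 40, 3), 1234.0))
        mean, n = extract_roi_mean(pmap, ROISpec((20.0, 20.0), (0, 1, 2)))
        assert mean == 1234.0
        assert n > 0

    @pytest.mark.parametrize("center", [(20.0, 20.0), (20.5, 20.5), (19.7, 21.2)])
    def test_count_matches_grid_enumeration_oracle(self, center):
        pmap = make_map(np.full((40, 40, 1), 1.0))
        _, n = extract_roi_mean(pmap, ROISpec(center, (0,)))
        # oracle: exhaustive scan of integer-center pixels
        cx, cy = center
        count = sum(
            1
            for i in range(40)
            for j in range(40)
            if (i - cx) ** 2 + (j - cy) ** 2 <= 4.0**2
        )
        assert n == count

    def test_masked_voxels_excluded(self):
        t1 = np.full((40, 40, 1), 100.0)
        mask = np.ones(t1.shape, dtype=bool)
        mask[20, 20, 0] = False
        t1[20, 20, 0] = 1e9  # must not contribute
        pmap = make_map(t1, mask=mask)
        mean, n = extract_roi_mean(pmap, ROISpec((20.0, 20.0), (0,)))
        assert mean == 100.0

    def test_fully_masked_roi_raises(self):
        pmap = make_map(
            np.full((40, 40, 1), 300.0), mask=np.zeros((40, 40, 1), dtype=bool)
        )
        with pytest.raises(ValueError, match="unmasked"):
            extract_roi_mean(pmap, ROISpec((20.0, 20.0), (0,)))

    def test_roi_outside_volume_rejected(self):
        pmap = make_map(np.full((40, 40, 1), 1.0))
        with pytest.raises(ValueError):
            extract_roi_mean(pmap, ROISpec((60.0, 20.0), (0,)))
        with pytest.raises(ValueError):
            extract_roi_mean(pmap, ROISpec((20.0, 20.0), (5,)))


class TestTestRetestVariation:
    def test_identical_pairs_zero(self):
        assert retest_variation([(100.0, 100.0), (50.0, 50.0)]) == 0.0

    def test_single_pair_hand_value(self):
        # |100-110| / 105 * 100
        assert retest_variation([(100.0, 110.0)]) == pytest.approx(
            10.0 / 105.0 * 100.0, rel=1e-12
        )

    def test_two_pair_hand_value(self):
        expected = (10.0 / 105.0 * 100.0 + 10.0 / 195.0 * 100.0) / 2.0
        assert retest_variation([(100, 110), (200, 190)]) == pytest.approx(
            expected, rel=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            retest_variation([(100.0, -5.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retest_variation(np.empty((0, 2)))

    @given(
        st.lists(
            st.tuples(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_property(self, pairs):
        v = retest_variation(pairs)
        assert 0.0 <= v <= 200.0
        if all(a == b for a, b in pairs):
            assert v == 0.0
        if v == 0.0:
            assert all(a == b for a, b in pairs)


class TestCV:
    def test_constant_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0, rel=1e-12)

    def test_scale_invariance(self):
        v = [3.0, 4.0, 6.5, 5.5]
        assert coefficient_of_variation(v) == pytest.approx(
            coefficient_of_variation([7.7 * x for x in v]), rel=1e-12
        )

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestPercentDeviation:
    def test_equal_zero(self):
        assert percent_deviation(1000.0, 1000.0) == 0.0

    def test_hand_value(self):
        assert percent_deviation(900.0, 1000.0) == -10.0

    def test_within_ten_percent_band(self):
        assert abs(percent_deviation(1050.0, 1000.0)) <= 10.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_deviation(900.0, 0.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([(100.0, 100.0), (50.0, 50.0)])
        assert ba.mean_diff_pct == 0.0
        assert ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_hand_value_symmetric_pairs(self):
        ba = bland_altman([(100.0, 110.0), (110.0, 100.0)])
        x = 10.0 / 105.0 * 100.0
        assert ba.mean_diff_pct == pytest.approx(0.0, abs=1e-12)
        # sample SD of {-x, +x} is x * sqrt(2)
        assert ba.sd_diff_pct == pytest.approx(x * np.sqrt(2.0), rel=1e-12)
        assert ba.loa_upper == pytest.approx(1.96 * x * np.sqrt(2.0), rel=1e-12)
        assert ba.loa_lower == pytest.approx(-1.96 * x * np.sqrt(2.0), rel=1e-12)

    def test_antisymmetry(self):
        pairs = [(100.0, 104.0), (98.0, 95.0), (210.0, 200.0)]
        fwd = bland_altman(pairs)
        rev = bland_altman([(b, a) for a, b in pairs])
        np.testing.assert_allclose(rev.diffs_pct, -fwd.diffs_pct)
        assert rev.mean_diff_pct == pytest.approx(-fwd.mean_diff_pct)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(100.0, 105.0)])


class TestRegionSummary:
    def test_200_voxel_region_volume(self):
        t1 = np.full((20, 20, 1), 1000.0)
        labels = np.zeros((20, 20, 1), dtype=int)
        labels[:10, :20, 0] = 1  # 200 voxels
        pmap = make_map(t1)
        df = region_summary(pmap, labels)
        row = df[df.label == 1].iloc[0]
        assert row.n_voxels == 200
        assert row.volume_cm3 == pytest.approx(1.000, rel=1e-12)

    def test_uniform_region_sd_zero(self):
        t1 = np.full((10, 10, 1), 777.0)
        labels = np.ones((10, 10, 1), dtype=int)
        df = region_summary(make_map(t1), labels)
        assert df.iloc[0].t1_mean == 777.0
        assert df.iloc[0].t1_sd == 0.0

    def test_empty_region_missing_not_raising(self):
        t1 = np.full((10, 10, 1), 777.0)
        labels = np.ones((10, 10, 1), dtype=int)
        mask = np.zeros(t1.shape, dtype=bool)
        df = region_summary(make_map(t1, mask=mask), labels)
        assert df.iloc[0].n_voxels == 0
        assert np.isnan(df.iloc[0].t1_mean)

    def test_label_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            region_summary(make_map(np.ones((4, 4, 1))), np.zeros((5, 5, 1), dtype=int))


class TestAgeTrend:
    def test_exact_linear(self):
        res = age_trend([20, 40, 60], [1000.0, 1010.0, 1020.0])
        assert res.slope == pytest.approx(0.5, rel=1e-12)
        assert res.intercept == pytest.approx(990.0, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.uniform(20, 80, n)
            if np.ptp(x) == 0:
                continue
            y = rng.uniform(500, 2000, n)
            res = age_trend(x, y)
            # closed-form normal equations
            X = np.column_stack([x, np.ones(n)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.slope == pytest.approx(beta[0], rel=1e-9, abs=1e-9)
            assert res.intercept == pytest.approx(beta[1], rel=1e-9, abs=1e-9)

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError):
            age_trend([30, 30, 30], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            age_trend([20, 40], [1.0, 2.0])


def _example_table():
    records = []
    rng = np.random.default_rng(3)
    for day in (0, 30, 99):
        for unit, base in (("40% PVP", 660.0), ("FBG", 1320.0)):
            for repeat in ("test", "retest"):
                records.append(
                    dict(
                        session_day=day,
                        repeat=repeat,
                        unit=unit,
                        metric="t1_ms",
                        value=base * (1 + 0.005 * rng.standard_normal()),
                    )
                )
    return MeasurementTable.from_records(records)


class TestMeasurementTable:
    def test_duplicate_rows_rejected(self):
        rec = dict(session_day=0, repeat="test", unit="a", metric="t1_ms", value=1.0)
        with pytest.raises(ValueError, match="duplicate"):
            MeasurementTable.from_records([rec, rec])

    def test_bad_repeat_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            MeasurementTable.from_records(
                [dict(session_day=0, repeat="again", unit="a", metric="t1_ms", value=1.0)]
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MeasurementTable.from_records(
                [dict(session_day=0, repeat="test", unit="a", metric="t1_ms",
                      value=np.nan)]
            )

    def test_csv_round_trip(self, tmp_path):
        table = _example_table()
        path = tmp_path / "m.csv"
        table.to_csv(path)
        loaded = MeasurementTable.from_csv(path)
        pd.testing.assert_frame_equal(loaded.df, table.df)

    def test_paired(self):
        table = _example_table()
        pairs = table.paired("40% PVP", "t1_ms")
        assert pairs.shape == (3, 2)


class TestQAReport:
    def test_completeness(self):
        table = _example_table()
        report = qa_report(table)
        assert len(report) == len(table.units()) * len(table.metrics())
        assert set(report.unit) == set(table.units())
        # one row per unit/metric
        assert not report.duplicated(subset=["unit", "metric"]).any()

    def test_reference_deviation(self):
        table = _example_table()
        ref = {"40% PVP": {"t1_ms": 656.0}, "FBG": {"t1_ms": 1321.0}}
        report = qa_report(table, reference=ref)
        row = report[(report.unit == "40% PVP")].iloc[0]
        measured = table.df[table.df.unit == "40% PVP"].value.mean()
        assert row.deviation_pct == pytest.approx(
            (measured - 656.0) / 656.0 * 100.0, rel=1e-12
        )

    def test_noise_monotonicity_property(self):
        # measurement-level version of the pipeline property: larger noise
        # gives larger median test-retest variation and CV over 50 seeds
        base = 1000.0
        med_var = []
        med_cv = []
        for sd in (1.0, 5.0, 25.0):
            variations = []
            cvs = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                pairs = base + sd * rng.standard_normal((5, 2))
                variations.append(retest_variation(pairs))
                cvs.append(coefficient_of_variation(pairs.mean(axis=1)))
            med_var.append(np.median(variations))
            med_cv.append(np.median(cvs))
        assert med_var[0] <= med_var[1] <= med_var[2]
        assert med_cv[0] <= med_cv[1] <= med_cv[2]

    def test_fbg_spatial_heterogeneity(self):
        # four FBG ROIs with distinct true values: across-ROI CV exceeds
        # any single-ROI test-retest variation
        rng = np.random.default_rng(9)
        true_vals = [38.0, 41.0, 44.0, 47.0]
        per_roi_pairs = {}
        for i, v in enumerate(true_vals):
            pairs = v + 0.05 * rng.standard_normal((6, 2))
            per_roi_pairs[i] = pairs
        single_roi_variations = [
            retest_variation(p) for p in per_roi_pairs.values()
        ]
        across = coefficient_of_variation(
            [p.mean() for p in per_roi_pairs.values()]
        )
        assert across > max(single_roi_variations)
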