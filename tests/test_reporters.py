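import numpy as np
import pandas as pd
import pytest

from obsight import reporters as rep
from obsight.synthetic import generate_dose_response


def make_plate(gfp, od, time_h=None, meta=None):
    gfp = np.atleast_2d(np.asarray(gfp, dtype=float))
    od = np.atleast_2d(np.asarray(od, dtype=float))
    if time_h is None:
        time_h = np.arange(gfp.shape[1], dtype=float)
    if meta is None:
        meta = pd.DataFrame(
            {
                "well": [f"W{i}" for i in range(gfp.shape[0])],
                "strain": "s1",
                "compound": "analyte",
                "concentration_uM": 0.0,
                "replicate": 1,
            }
        )
    return rep.PlateTimeSeries(gfp=gfp, od600=od, time_h=time_h, well_meta=meta)


class TestPerCellSignal:
    def test_elementwise_ratio(self):
        plate = make_plate([[1000.0, 1200.0]], [[0.5, 0.6]])
        np.testing.assert_allclose(
            rep.per_cell_signal(plate), [[2000.0, 2000.0]]
        )

    def test_od_doubling_with_gfp_constant_signal(self):
        od = np.array([[0.1 * 2**t for t in range(5)]])
        plate = make_plate(od * 500.0, od)
        np.testing.assert_allclose(rep.per_cell_signal(plate), 500.0)

    def test_death_cutoff_masks_values(self):
        plate = make_plate([[100.0, 100.0, 100.0]], [[0.5, 0.4, 0.05]])
        out = rep.per_cell_signal(plate, od_min=0.1)
        assert np.isnan(out[0, 2]) and not np.isnan(out[0, :2]).any()

    def test_commutes_with_time_subsetting(self):
        rng = np.random.default_rng(0)
        gfp = rng.uniform(100, 1000, (3, 8))
        od = rng.uniform(0.1, 1.0, (3, 8))
        full = rep.per_cell_signal(make_plate(gfp, od))
        sub = rep.per_cell_signal(make_plate(gfp[:, 2:5], od[:, 2:5],
                                             time_h=np.arange(3.0)))
        np.testing.assert_allclose(full[:, 2:5], sub)


class TestReporterFoldChange:
    def test_equal_and_double(self):
        s = np.array([100.0, 200.0])
        fc, _ = rep.reporter_fold_change(s, s)
        np.testing.assert_allclose(fc, 1.0)
        fc, _ = rep.reporter_fold_change(2 * s, s)
        np.testing.assert_allclose(fc, 2.0)

    def test_delta_method_variance(self):
        t, c = np.array([200.0]), np.array([100.0])
        sd_t, sd_c = np.array([10.0]), np.array([5.0])
        _, sd = rep.reporter_fold_change(t, c, sd_t, sd_c)
        expected = 2.0 * np.sqrt((10 / 200) ** 2 + (5 / 100) ** 2)
        assert sd[0] == pytest.approx(expected)

    def test_against_sampling_oracle(self):
        # first-order propagation vs brute-force Monte Carlo on small CVs
        rng = np.random.default_rng(1)
        t_draws = rng.normal(500.0, 10.0, 200_000)
        c_draws = rng.normal(250.0, 5.0, 200_000)
        _, sd = rep.reporter_fold_change(
            np.array([500.0]), np.array([250.0]), np.array([10.0]), np.array([5.0])
        )
        assert sd[0] == pytest.approx(np.std(t_draws / c_draws), rel=0.05)


class TestMaxFoldChangeTimepoint:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([1.0, 1.5, 2.0, 2.5], 3),  # monotone rising -> last
            ([1.0, 3.0, 1.5, 1.2], 1),  # interior peak
            ([2.0, 1.0, 2.0], 0),  # tie -> earliest
        ],
    )
    def test_peak_location(self, series, expected):
        assert rep.max_fold_change_timepoint(np.array(series)) == expected


class TestHillFit:
    def test_noiseless_recovery(self):
        c = np.geomspace(0.05, 20, 6)
        y = rep.hill(c, 100.0, 200.0, 1.0, 2.0)
        fit = rep.fit_hill(c, y)
        assert fit.y_min == pytest.approx(100.0, abs=1e-5)
        assert fit.y_max == pytest.approx(200.0, abs=1e-5)
        assert fit.K_M == pytest.approx(1.0, abs=1e-6)
        assert fit.n == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_identity(self):
        fit = rep.HillFit(50.0, 350.0, 0.7, 3.3, 0.0)
        y_mid = rep.hill(fit.K_M, fit.y_min, fit.y_max, fit.K_M, fit.n)
        assert y_mid == pytest.approx((fit.y_min + fit.y_max) / 2)

    def test_repressed_reporter_direction_free(self):
        c = np.geomspace(0.05, 20, 8)
        y = rep.hill(c, 1000.0, 300.0, 0.8, 1.5)  # y_max < y_min: repression
        fit = rep.fit_hill(c, y)
        assert fit.y_max < fit.y_min
        assert fit.K_M == pytest.approx(0.8, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            rep.fit_hill(np.array([0.1, 1.0, 1.0, 10.0]), np.ones(4) * 100)


class TestInvertHill:
    def test_midpoint_maps_to_km(self):
        fit = rep.HillFit(100.0, 200.0, 1.3, 2.5, 0.0)
        assert rep.invert_hill(fit, 150.0) == pytest.approx(1.3)

    def test_roundtrip_identity(self):
        fit = rep.HillFit(80.0, 260.0, 0.6, 4.5, 0.0)
        for c in [0.05, 0.3, 0.6, 1.2, 5.0]:
            y = rep.hill(c, fit.y_min, fit.y_max, fit.K_M, fit.n)
            assert rep.invert_hill(fit, y) == pytest.approx(c, abs=1e-10)

    def test_saturated_signal_rejected(self):
        fit = rep.HillFit(100.0, 200.0, 1.0, 2.0, 0.0)
        with pytest.raises(ValueError, match="saturated"):
            rep.invert_hill(fit, 200.0)
        with pytest.raises(ValueError, match="saturated"):
            rep.invert_hill(fit, 90.0)


class TestGrowthStats:
    def test_clean_doubling(self):
        t = np.linspace(0, 1, 5)
        od = 0.1 * 2**t
        stats = rep.growth_stats(od, t)
        assert stats["growth_rate_per_h"] == pytest.approx(np.log(2), rel=1e-6)
        assert stats["doubling_time_h"] == pytest.approx(1.0, rel=1e-6)

    def test_flat_culture_flagged(self):
        stats = rep.growth_stats(np.full(6, 0.2), np.arange(6.0))
        assert stats["growth_rate_per_h"] == 0.0
        assert not stats["doubling_defined"]

    def test_matches_log_linear_regression_oracle(self):
        from scipy.stats import linregress

        rng = np.random.default_rng(2)
        t = np.linspace(0, 5, 20)
        od = 0.05 * np.exp(0.6 * t) * np.exp(rng.normal(0, 0.003, t.size))
        stats = rep.growth_stats(od, t)
        oracle = linregress(t, np.log(od)).slope
        assert stats["growth_rate_per_h"] == pytest.approx(oracle, rel=0.05)
        assert stats["growth_rate_per_h"] == pytest.approx(0.6, rel=0.05)

    def test_lag_and_plateau_phases_detected_approximately(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 10, 40)
        rate = 0.6
        od = np.minimum(0.05 * np.exp(rate * np.maximum(t - 2, 0)), 1.2)
        od *= np.exp(rng.normal(0, 0.002, t.size))
        stats = rep.growth_stats(od, t)
        # the detected window may clip a transition point or two
        assert stats["growth_rate_per_h"] == pytest.approx(rate, rel=0.15)


class TestCompoundCorrelation:
    def test_identical_and_negated(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 10))
        np.testing.assert_allclose(rep.compound_correlation(X, X), 1.0, atol=1e-12)
        np.testing.assert_allclose(rep.compound_correlation(X, -X), -1.0, atol=1e-12)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(3, 12)), rng.normal(size=(3, 12))
        ours = rep.compound_correlation(A, B)
        oracle = [np.corrcoef(A[i], B[i])[0, 1] for i in range(3)]
        np.testing.assert_allclose(ours, oracle, atol=1e-12)


class TestTransferCurvePipeline:
    def test_end_to_end_hill_from_synthetic_plate(self):
        # build a plate: one strain, 6 concentrations x 2 replicates
        true = rep.HillFit(200.0, 800.0, 1.0, 2.0, 0.0)
        concs = np.array([0.0, 0.14, 0.28, 0.56, 1.12, 2.24])
        time_h = np.linspace(0, 6, 7)
        wells, meta_rows = [], []
        for i, c in enumerate(concs):
            level = rep.hill(np.array([c]), *[true.y_min, true.y_max, true.K_M, true.n])[0]
            for r in (1, 2):
                od = 0.1 * np.exp(0.4 * time_h)
                gfp = level * od  # per-cell signal == level at every time
                wells.append((gfp, od))
                meta_rows.append(
                    {"well": f"W{i}{r}", "strain": "s1", "compound": "mal",
                     "concentration_uM": c, "replicate": r}
                )
        plate = rep.PlateTimeSeries(
            gfp=np.vstack([w[0] for w in wells]),
            od600=np.vstack([w[1] for w in wells]),
            time_h=time_h,
            well_meta=pd.DataFrame(meta_rows),
        )
        curve = rep.transfer_curve(plate, "s1", "mal")
        fit = rep.fit_hill(curve["concentration_uM"], curve["mean"])
        assert fit.K_M == pytest.approx(1.0, rel=1e-3)
        assert fit.n == pytest.approx(2.0, rel=1e-3)

    def test_long_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        time_h = np.arange(4.0)
        rows = []
        for w in ("A1", "A2"):
            for t in time_h:
                rows.append({"well": w, "time_h": t,
                             "od600": rng.uniform(0.1, 1), "gfp": rng.uniform(100, 900)})
        pd.DataFrame(rows).to_csv(tmp_path / "plate.csv", index=False)
        pd.DataFrame(
            {"well": ["A1", "A2"], "strain": "s", "compound": "m",
             "concentration_uM": [0.0, 1.0], "replicate": [1, 1]}
        ).to_csv(tmp_path / "map.csv", index=False)
        plate = rep.PlateTimeSeries.from_long_csv(tmp_path / "plate.csv", tmp_path / "map.csv")
        assert plate.gfp.shape == (2, 4)
        assert list(plate.well_meta["well"]) == ["A1", "A2"]


class TestDoseResponseGenerator:
    def test_zero_noise_exact(self):
        fit = rep.HillFit(100.0, 200.0, 1.0, 2.0, 0.0)
        c = np.geomspace(0.1, 10, 5)
        out = generate_dose_response(fit, c, noise_cv=0.0, reps=2, seed=0)
        expected = rep.hill(c, 100.0, 200.0, 1.0, 2.0)
        np.testing.assert_allclose(out, np.tile(expected, (2, 1)))

    def test_seeded_reproducibility(self):
        fit = rep.HillFit(100.0, 200.0, 1.0, 2.0, 0.0)
        c = np.geomspace(0.1, 10, 5)
        a = generate_dose_response(fit, c, noise_cv=0.05, reps=3, seed=4)
        b = generate_dose_response(fit, c, noise_cv=0.05, reps=3, seed=4)
        np.testing.assert_array_equal(a, b)
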