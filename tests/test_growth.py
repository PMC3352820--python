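"""Blank correction, OD calibration, V_MAX estimation, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoevo.growth import (
    CalibrationModel,
    GrowthCurve,
    IsolateLabel,
    blank_correct,
    carrying_capacity,
    curves_from_table,
    estimate_vmax,
    fit_od_calibration,
    od_to_log_density,
    treatment_contrast,
    vmax_table,
)
from ecoevo.synthetic import simulate_growth_curve


def _plate(rows):
    return pd.DataFrame.from_records(rows)


class TestBlankCorrect:
    def test_simple_subtraction_and_floor(self):
        df = _plate(
            [
                {"plate": "P", "well": "A1", "time_h": 0.0, "od600": 0.30,
                 "is_control": False},
                {"plate": "P", "well": "B1", "time_h": 0.0, "od600": 0.04,
                 "is_control": False},
                {"plate": "P", "well": "H1", "time_h": 0.0, "od600": 0.05,
                 "is_control": True},
            ]
        )
        out = blank_correct(df, epsilon=0.001)
        vals = out.sort_values("well")["od_corrected"].to_numpy()
        np.testing.assert_allclose(vals, [0.25, 0.001])

    def test_missing_control_lists_offenders(self):
        df = _plate(
            [{"plate": "P", "well": "A2", "time_h": 0.0, "od600": 0.3,
              "is_control": False}]
        )
        with pytest.raises(ValueError, match="P"):
            blank_correct(df)

    def test_recovers_generator_truth_without_noise(self, tiny_config):
        rows = simulate_growth_curve(tiny_config, IsolateLabel("A", "ancestral", 1))
        out = blank_correct(rows, epsilon=1e-6)
        # noiseless: corrected OD equals the calibration-line OD of N(t)
        i = 0
        dens_log10 = (
            tiny_config.cal_intercepts[i]
            + tiny_config.cal_slope * out.sort_values("time_h")["od_corrected"]
        )
        assert dens_log10.iloc[0] == pytest.approx(np.log10(tiny_config.n0), rel=1e-6)


class TestCalibration:
    def test_exact_recovery_from_noiseless_lines(self):
        rows = []
        for sp, a in (("A", 5.0), ("B", 6.0)):
            for od in (0.1, 0.5, 1.0):
                rows.append(
                    {"species": sp, "od600": od,
                     "colonies_per_ml": 10 ** (a + 3.0 * od)}
                )
        model = fit_od_calibration(pd.DataFrame(rows))
        assert model.slope == pytest.approx(3.0, abs=1e-9)
        assert model.intercepts["A"] == pytest.approx(5.0, abs=1e-9)
        assert model.intercepts["B"] == pytest.approx(6.0, abs=1e-9)
        assert model.r2 == pytest.approx(1.0)

    def test_requires_od_variation(self):
        rows = [
            {"species": "A", "od600": 0.5, "colonies_per_ml": 1e6},
            {"species": "A", "od600": 0.5, "colonies_per_ml": 2e6},
        ]
        with pytest.raises(ValueError):
            fit_od_calibration(pd.DataFrame(rows))

    def test_od_to_log_density_intercept_and_offsets(self):
        model = CalibrationModel(slope=3.0, intercepts={"A": 5.0, "B": 6.0})
        assert od_to_log_density(model, 0.0, "A") == pytest.approx(
            5.0 * np.log2(10.0)
        )
        diff = od_to_log_density(model, 0.4, "B") - od_to_log_density(model, 0.4, "A")
        assert diff == pytest.approx(1.0 * np.log2(10.0))
        with pytest.raises(KeyError):
            od_to_log_density(model, 0.1, "Z")

    def test_slope_ci_covers_truth_in_simulation(self):
        # direct coverage check at modest replication; the full 500-rep
        # study runs in the acceptance suite
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(0)
        hits = 0
        reps = 100
        for _ in range(reps):
            rows = []
            for sp, a in (("A", 5.0), ("B", 6.0)):
                od = rng.uniform(0.1, 1.2, size=40)
                y = a + 3.0 * od + rng.normal(0, 0.15, size=40)
                rows += [{"species": sp, "od600": o, "colonies_per_ml": 10 ** v}
                         for o, v in zip(od, y)]
            df = pd.DataFrame(rows)
            df["_y"] = np.log10(df.colonies_per_ml)
            fit = smf.ols("_y ~ C(species) + od600", data=df).fit()
            lo, hi = fit.conf_int().loc["od600"]
            hits += lo <= 3.0 <= hi
        assert 0.85 <= hits / reps <= 1.0


class TestVmax:
    def test_exact_one_doubling_per_day(self):
        curve = GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=[0.0, 24.0, 48.0], log2_density=[10.0, 11.0, 12.0],
        )
        est = estimate_vmax(curve)
        assert est.vmax == pytest.approx(1.0)

    def test_hand_ols_case(self):
        curve = GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=[0.0, 24.0, 48.0], log2_density=[10.0, 12.0, 13.0],
        )
        assert estimate_vmax(curve).vmax == pytest.approx(1.5)

    def test_window_excludes_late_points(self):
        curve = GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=[0.0, 24.0, 48.0, 72.0, 96.0],
            log2_density=[10.0, 11.0, 12.0, 12.0, 12.0],
        )
        assert estimate_vmax(curve, window_h=48.0).vmax == pytest.approx(1.0)

    def test_saturated_fit_reports_zero_se(self):
        curve = GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=[0.0, 24.0], log2_density=[10.0, 11.0],
        )
        assert estimate_vmax(curve).se == 0.0

    def test_too_few_points_in_window(self):
        curve = GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=[0.0, 72.0], log2_density=[10.0, 11.0],
        )
        with pytest.raises(ValueError):
            estimate_vmax(curve, window_h=48.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-30, 30))
    def test_invariant_to_density_offset(self, shift):
        t = [0.0, 24.0, 48.0]
        y = np.array([10.0, 11.4, 12.1])
        base = estimate_vmax(
            GrowthCurve(IsolateLabel("A", "ancestral", 1), "unused", t, None, None, y)
        ).vmax
        shifted = estimate_vmax(
            GrowthCurve(IsolateLabel("A", "ancestral", 1), "unused", t, None, None,
                        y + shift)
        ).vmax
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_noiseless_exponential_recovers_rate(self, tiny_config):
        cfg = tiny_config
        cfg.K = np.array([np.inf, np.inf])
        rows = simulate_growth_curve(cfg, IsolateLabel("A", "ancestral", 1))
        corrected = blank_correct(rows, epsilon=1e-9)
        table = vmax_table(corrected, cfg.calibration_model())
        assert table.loc[0, "vmax"] == pytest.approx(cfg.r[0], abs=1e-6)


class TestCarryingCapacity:
    def _curve(self, times):
        n = len(times)
        return GrowthCurve(
            IsolateLabel("A", "ancestral", 1), "unused",
            times_h=times, log2_density=np.linspace(20, 25, n),
        )

    def test_reads_96h_point(self):
        c = self._curve([0.0, 24.0, 48.0, 72.0, 96.0])
        assert carrying_capacity(c) == pytest.approx(25.0 / np.log2(10.0))

    def test_tolerance_rule(self):
        c = self._curve([0.0, 95.0])
        assert carrying_capacity(c, tol_h=2.0) == pytest.approx(25.0 / np.log2(10.0))
        with pytest.raises(ValueError):
            carrying_capacity(self._curve([0.0, 48.0]))


class TestTreatmentContrast:
    def test_identical_groups(self):
        res = treatment_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.difference == 0.0 and res.p == 1.0

    def test_shifted_groups_hit_enumeration_floor(self):
        res = treatment_contrast([11.0, 12.0, 13.0], [1.0, 2.0, 3.0],
                                 exhaustive=True)
        assert res.p == pytest.approx(2.0 / 20.0)

    def test_positive_contrast_orientation(self):
        # evolved group passed first: faster growth gives a positive difference
        res = treatment_contrast([2.0, 2.2, 2.4], [1.0, 1.1, 1.2])
        assert res.difference > 0
        assert res.ratio > 1

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            treatment_contrast([1.0], [1.0, 2.0])


def test_curves_from_table_groups_by_isolate(community):
    rows = []
    for rep in (1, 2):
        rows.append(
            simulate_growth_curve(
                community, IsolateLabel("A", "ancestral", rep), seed=rep
            )
        )
    df = blank_correct(pd.concat(rows, ignore_index=True))
    curves = curves_from_table(df, community.calibration_model())
    assert len(curves) == 2
    assert {c.isolate.replicate for c in curves} == {1, 2}
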