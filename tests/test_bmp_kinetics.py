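import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biovalor import bmp_kinetics as bk
from biovalor import synthetic_data as synth


class TestFirstOrderCurve:
    def test_zero_at_origin(self):
        assert bk.first_order_curve(0.0, 0.204, 0.57) == pytest.approx(0.0)

    def test_half_life_identity(self):
        k = 0.57
        assert bk.first_order_curve(math.log(2) / k, 0.204, k) == pytest.approx(0.102)

    def test_reference_day25(self):
        assert bk.first_order_curve(25.0, 0.204, 0.57) == pytest.approx(0.20399, abs=1e-5)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            bk.first_order_curve(-1.0, 0.2, 0.5)


class TestGompertzCurve:
    def test_value_at_lag_point(self):
        b0 = 0.204
        val = bk.gompertz_curve(3.0, b0, 76.12, 3.0)
        assert val == pytest.approx(b0 * math.exp(-math.e), rel=1e-12)
        assert val == pytest.approx(0.06599 * b0, abs=1e-5)

    def test_asymptote(self):
        assert bk.gompertz_curve(1e6, 0.204, 76.12, 0.0) == pytest.approx(0.204, rel=1e-9)

    def test_zero_lag_value_at_origin(self):
        b0 = 0.204
        rm = 76.12
        expected = b0 * math.exp(-math.exp(rm * 1e-3 * math.e / b0 * 0.0 + 1.0))
        assert bk.gompertz_curve(0.0, b0, rm, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_b0_rejected(self):
        with pytest.raises(ValueError):
            bk.gompertz_curve(1.0, 0.0, 50.0, 0.0)


class TestKnnImpute:
    def test_hand_computed_inverse_distance_example(self):
        series = pd.Series(
            {1: 50.0, 4: 60.0, 5: np.nan, 6: 60.0, 10: 50.0}
        ).sort_index()
        out = bk.knn_impute_composition(series, k=4)
        # (50/4 + 60/1 + 60/1 + 50/5) / (1/4 + 1 + 1 + 1/5)
        assert out.loc[5] == pytest.approx(142.5 / 2.45, abs=1e-12)
        assert out.loc[5] == pytest.approx(58.16, abs=0.005)

    def test_equal_neighbours_give_common_value(self):
        series = pd.Series({1: 0.6, 2: 0.6, 3: np.nan, 4: 0.6, 5: 0.6})
        out = bk.knn_impute_composition(series, k=4)
        assert out.loc[3] == pytest.approx(0.6)

    def test_k1_is_nearest_value_carry(self):
        series = pd.Series({1: 10.0, 2: np.nan, 7: 99.0})
        out = bk.knn_impute_composition(series, k=1)
        assert out.loc[2] == pytest.approx(10.0)

    def test_observed_values_unchanged(self):
        series = pd.Series({1: 0.5, 4: 0.7, 6: np.nan, 10: 0.9, 14: 0.8})
        out = bk.knn_impute_composition(series, k=4)
        for day in (1, 4, 10, 14):
            assert out.loc[day] == series.loc[day]

    def test_too_few_observations_rejected(self):
        series = pd.Series({1: 0.5, 2: np.nan, 3: np.nan})
        with pytest.raises(ValueError):
            bk.knn_impute_composition(series, k=4)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            bk.knn_impute_composition(pd.Series({1: np.nan, 2: np.nan}), k=1)


class TestBlankCorrect:
    def test_bottle_identical_to_blank_nets_zero(self, daily_schedule):
        blank_kp = synth.KineticParams("first_order", b0=0.02, k=0.1)
        conditions = {
            "cond": (blank_kp, synth.BottleSpec("cond", vs_feedstock=0.0, vs_inoculum=3.33, seed=1, is_blank=False)),
        }
        blank_spec = synth.BottleSpec("blank", vs_feedstock=0.0, vs_inoculum=3.33, seed=2)
        ds = synth.gen_bmp_experiment(conditions, blank_spec, daily_schedule, blank_params=blank_kp)
        net = bk.blank_correct(ds)["cond"]
        assert np.allclose(net["net_ch4_mL"], 0.0, atol=1e-9)

    def test_replicates_averaged(self):
        days = [0.0, 25.0]
        readings = []
        for bid, final in (("c_1", 40.0), ("c_2", 44.0)):
            for day, val in zip(days, [0.0, final]):
                readings.append(
                    dict(day=day, bottle_id=bid, condition="c",
                         cum_biogas_mL=val * 2, cum_ch4_mL=val, ch4_frac=np.nan)
                )
        for day in days:
            readings.append(
                dict(day=day, bottle_id="blank_1", condition="blank",
                     cum_biogas_mL=0.0, cum_ch4_mL=0.0, ch4_frac=np.nan)
            )
        bottles = pd.DataFrame(
            [
                dict(bottle_id="c_1", condition="c", vs_feedstock=1.0, vs_inoculum=3.0, is_blank=False),
                dict(bottle_id="c_2", condition="c", vs_feedstock=1.0, vs_inoculum=3.0, is_blank=False),
                dict(bottle_id="blank_1", condition="blank", vs_feedstock=0.0, vs_inoculum=3.0, is_blank=True),
            ]
        )
        ds = bk.BMPDataset(pd.DataFrame(readings), bottles)
        net = bk.blank_correct(ds)["c"]
        assert net.loc[25.0, "net_ch4_mL"] == pytest.approx(42.0)

    def test_blank_above_bottle_clipped_to_zero(self, caplog):
        days = [0.0, 10.0]
        rows = []
        for day, val in zip(days, [0.0, 5.0]):
            rows.append(dict(day=day, bottle_id="c_1", condition="c",
                             cum_biogas_mL=val, cum_ch4_mL=val, ch4_frac=np.nan))
        for day, val in zip(days, [0.0, 9.0]):
            rows.append(dict(day=day, bottle_id="b_1", condition="blank",
                             cum_biogas_mL=val, cum_ch4_mL=val, ch4_frac=np.nan))
        bottles = pd.DataFrame(
            [
                dict(bottle_id="c_1", condition="c", vs_feedstock=1.0, vs_inoculum=3.0, is_blank=False),
                dict(bottle_id="b_1", condition="blank", vs_feedstock=0.0, vs_inoculum=3.0, is_blank=True),
            ]
        )
        ds = bk.BMPDataset(pd.DataFrame(rows), bottles)
        with caplog.at_level("WARNING"):
            net = bk.blank_correct(ds)["c"]
        assert net.loc[10.0, "net_ch4_mL"] == 0.0
        assert any("clipped" in rec.message for rec in caplog.records)

    def test_no_blank_rejected(self, noiseless_dataset):
        stripped = bk.BMPDataset(
            noiseless_dataset.readings[noiseless_dataset.readings["condition"] != "blank"],
            noiseless_dataset.bottles[~noiseless_dataset.bottles["is_blank"]],
        )
        with pytest.raises(ValueError):
            bk.blank_correct(stripped)

    def test_inoculum_scaling(self, daily_schedule):
        # bottle with double the blank's inoculum gets double the subtraction
        blank_kp = synth.KineticParams("first_order", b0=0.02, k=0.1)
        conditions = {
            "cond": (blank_kp, synth.BottleSpec("cond", vs_feedstock=0.0, vs_inoculum=6.66, seed=1, is_blank=False)),
        }
        blank_spec = synth.BottleSpec("blank", vs_feedstock=0.0, vs_inoculum=3.33, seed=2)
        ds = synth.gen_bmp_experiment(conditions, blank_spec, daily_schedule, blank_params=blank_kp)
        net = bk.blank_correct(ds)["cond"]
        assert np.allclose(net["net_ch4_mL"], 0.0, atol=1e-9)


class TestFitModel:
    def test_first_order_recovery(self):
        t = np.arange(0, 26, dtype=float)
        b = bk.first_order_curve(t, 0.204, 0.57)
        fit = bk.fit_model(t, b, "first_order")
        assert fit.converged
        assert fit.k == pytest.approx(0.57, abs=1e-3)
        assert fit.rmse < 1e-9

    def test_gompertz_recovery(self):
        t = np.arange(0, 26, dtype=float)
        b = bk.gompertz_curve(t, 0.204, 76.12, 0.0)
        fit = bk.fit_model(t, b, "gompertz")
        assert fit.rm == pytest.approx(76.12, abs=0.1)

    def test_three_points_rejected(self):
        with pytest.raises(ValueError):
            bk.fit_model([0.0, 1.0, 2.0], [0.0, 0.1, 0.15], "first_order")

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            bk.fit_model(np.arange(5.0), np.ones(5), "first_order")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            bk.fit_model(np.arange(5.0), np.arange(5.0) * 0.1, "logistic")

    def test_fitted_curve_monotone(self):
        t = np.arange(0, 26, dtype=float)
        b = bk.first_order_curve(t, 0.204, 0.57) + 0.002 * np.sin(t)
        b = np.maximum.accumulate(np.clip(b, 0, None))
        for model in ("first_order", "gompertz"):
            fit = bk.fit_model(t, b, model)
            dense = np.linspace(0, 25, 400)
            assert (np.diff(fit.predict(dense)) >= -1e-12).all()

    def test_models_agree_on_near_exponential_data(self):
        # with no lag, both models should describe the same curve comparably
        t = np.arange(0, 26, dtype=float)
        b = bk.first_order_curve(t, 0.133, 0.69)
        fo = bk.fit_model(t, b, "first_order")
        gz = bk.fit_model(t, b, "gompertz")
        assert fo.rmse < 1e-9
        assert gz.rmse < 0.03 * 0.133  # within a few % of the asymptote

    def test_grid_search_oracle_equivalence(self):
        t = np.arange(0, 26, 2.0)
        b = bk.first_order_curve(t, 0.18, 0.45) + 0.003 * np.cos(t / 3.0)
        b = np.maximum.accumulate(np.clip(b, 0, None))
        fit = bk.fit_model(t, b, "first_order")
        b0_grid = np.linspace(0.1, 0.3, 201)
        k_grid = np.linspace(0.05, 1.0, 191)
        sse = np.array(
            [
                [np.sum((b - bk.first_order_curve(t, b0, k)) ** 2) for k in k_grid]
                for b0 in b0_grid
            ]
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.rmse**2 * t.size <= sse[i, j] + 1e-12
        assert fit.b0 == pytest.approx(b0_grid[i], abs=(b0_grid[1] - b0_grid[0]))
        assert fit.k == pytest.approx(k_grid[j], abs=(k_grid[1] - k_grid[0]))

    def test_noisy_recovery_median_error(self):
        # 100 seeded replicates at 2% of B0 noise: median |k-hat - k|/k < 5%
        t = np.arange(0, 26, dtype=float)
        clean = bk.first_order_curve(t, 0.204, 0.57)
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(100):
            noisy = clean + rng.normal(0, 0.02 * 0.204, t.size)
            fit = bk.fit_model(t, noisy, "first_order")
            errors.append(abs(fit.k - 0.57) / 0.57)
        assert np.median(errors) < 0.05


class TestBmpSummary:
    @staticmethod
    def _net(final_ch4, final_biogas):
        return pd.DataFrame(
            {"net_ch4_mL": [0.0, final_ch4], "net_biogas_mL": [0.0, final_biogas]},
            index=[0.0, 25.0],
        )

    def test_zero_net_gives_zero_smp(self):
        comp = pd.Series({0: 0.5, 25: 0.5})
        out = bk.bmp_summary(self._net(0.0, 0.0), comp, vs_feedstock=1.0)
        assert out.smp == 0.0

    def test_constant_composition_gives_max_content(self):
        comp = pd.Series({0: 0.86, 25: 0.86})
        out = bk.bmp_summary(self._net(133.0, 567.0), comp, vs_feedstock=1.0)
        assert out.max_ch4_content == pytest.approx(86.0)

    def test_smp_matches_generator_b0(self, no_biochar_params, daily_schedule):
        spec = synth.BottleSpec("x", vs_feedstock=1.0, noise_sd=0.0, seed=0)
        blank_spec = synth.BottleSpec("blank", vs_feedstock=0.0, noise_sd=0.0, seed=1)
        ds = synth.gen_bmp_experiment({"x": (no_biochar_params, spec)}, blank_spec, daily_schedule)
        net = bk.blank_correct(ds)["x"]
        comp = ds.readings[ds.readings["condition"] == "x"].groupby("day")["ch4_frac"].mean()
        comp = bk.knn_impute_composition(comp, k=4)
        out = bk.bmp_summary(net, comp, vs_feedstock=1.0)
        assert out.smp == pytest.approx(0.204, abs=1e-3)
        assert out.smp <= out.sgp

    def test_biogas_yield_uses_density(self):
        comp = pd.Series({0: 0.5, 25: 0.5})
        out = bk.bmp_summary(self._net(300.0, 600.0), comp, vs_feedstock=1.0,
                             biogas_density_g_l=1.2)
        assert out.biogas_yield == pytest.approx(0.6 * 1.2)

    def test_zero_vs_rejected(self):
        comp = pd.Series({0: 0.5})
        with pytest.raises(ValueError):
            bk.bmp_summary(self._net(10.0, 20.0), comp, vs_feedstock=0.0)


@settings(max_examples=50, deadline=None)
@given(b0=st.floats(0.01, 1.0), k=st.floats(0.01, 3.0))
def test_first_order_monotone_property(b0, k):
    t = np.linspace(0, 30, 200)
    vals = bk.first_order_curve(t, b0, k)
    assert (np.diff(vals) >= -1e-15).all()
    assert vals.max() <= b0 + 1e-12


@settings(max_examples=50, deadline=None)
@given(b0=st.floats(0.01, 1.0), rm=st.floats(1.0, 200.0), lam=st.floats(0.0, 10.0))
def test_gompertz_monotone_and_bounded_property(b0, rm, lam):
    t = np.linspace(0, 50, 300)
    vals = bk.gompertz_curve(t, b0, rm, lam)
    assert (np.diff(vals) >= -1e-12).all()
    assert vals.max() <= b0 + 1e-12
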