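"""Storage-kinetics models, fits, and time-to-threshold solvers."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hygrostab import (AsymptoticFirstOrderParams, DomainError,
                       ExponentialDecayParams, FitError, KineticSeries,
                       NeverReachedError, ResponseKind, UnitError,
                       asymptotic_first_order, exp_decay,
                       fit_asymptotic_first_order, fit_exp_decay,
                       gen_kinetic_series, time_to_level_asymptotic,
                       time_to_level_decay)
from hygrostab.kinetics import read_kinetics_csv

# published fitted parameter rows: (response, ERH, params, time grid)
TABLE_ROWS = [
    ("moisture", 11, (3.5, 2.8, 0.08), np.arange(0, 20)),
    ("moisture", 32, (3.5, 5.8, 0.18), np.arange(0, 20)),
    ("moisture", 65, (3.3, 14.7, 0.15), np.arange(0, 31)),
    ("abs420", 11, (0.008, 0.124, 0.13), np.array([3, 10, 20, 30, 45, 60, 120])),
    ("abs420", 32, (0.005, 0.118, 0.08), np.array([3, 10, 20, 30, 45, 60, 120])),
    ("abs420", 65, (0.002, 0.101, 0.07), np.array([3, 10, 20, 30, 45, 60, 120])),
]

PH_ROWS = [
    (11, (5.07, 0.38)),
    (32, (5.07, 0.72)),
    (65, (5.08, 2.11)),
]


class TestForwardModels:
    def test_time_zero_returns_initial_value(self):
        p = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        assert asymptotic_first_order(p, 0.0) == pytest.approx(3.3)

    def test_long_time_approaches_equilibrium(self):
        p = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        assert asymptotic_first_order(p, 200.0) == pytest.approx(14.7, abs=1e-10)

    def test_humid_uptake_near_equilibrium_at_20_days(self):
        p = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        assert asymptotic_first_order(p, 20.0) == pytest.approx(14.13, abs=0.005)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 50, 200)
        for _ in range(25):
            y0, yinf = rng.uniform(0, 10, 2)
            if y0 == yinf:
                continue
            p = AsymptoticFirstOrderParams(y0, yinf, rng.uniform(0.01, 2))
            y = asymptotic_first_order(p, t)
            d = np.diff(y)
            # non-strict: increments underflow to zero on the plateau
            assert np.all(d >= 0) if yinf > y0 else np.all(d <= 0)
            assert np.all((y >= min(y0, yinf) - 1e-12)
                          & (y <= max(y0, yinf) + 1e-12))

    def test_decay_initial_and_zero_rate(self):
        assert exp_decay(ExponentialDecayParams(5.07, 0.1), 0.0) == 5.07
        assert exp_decay(ExponentialDecayParams(5.07, 0.0), 50.0) == 5.07

    def test_decay_direct_evaluation(self):
        p = ExponentialDecayParams(5.08, 2.11e-4)
        assert exp_decay(p, 135.0) == pytest.approx(4.94, abs=0.005)

    def test_param_validation(self):
        with pytest.raises(DomainError):
            AsymptoticFirstOrderParams(3.0, 3.0, 0.1)
        with pytest.raises(DomainError):
            AsymptoticFirstOrderParams(3.0, 4.0, 0.0)
        with pytest.raises(DomainError):
            ExponentialDecayParams(0.0, 0.1)


class TestFits:
    @pytest.mark.parametrize("response, erh, truth, times", TABLE_ROWS)
    def test_noiseless_round_trip(self, response, erh, truth, times):
        p = AsymptoticFirstOrderParams(*truth)
        s = gen_kinetic_series(p, times, 0.0, 1, 0, response, str(erh))[0]
        fit, diag = fit_asymptotic_first_order(s)
        assert fit.Y0 == pytest.approx(truth[0], rel=1e-3)
        assert fit.Yinf == pytest.approx(truth[1], rel=1e-3)
        assert fit.k == pytest.approx(truth[2], rel=1e-3)
        assert diag.rmse <= 1e-8

    @pytest.mark.parametrize("erh, truth", PH_ROWS)
    def test_ph_noiseless_round_trip(self, erh, truth, tmp_path):
        p = ExponentialDecayParams(*truth)
        t = np.linspace(0, 3.0, 13)  # several characteristic times of 1/k
        s = gen_kinetic_series(p, t, 0.0, 1, 0, "ph", str(erh))[0]
        fit, diag = fit_exp_decay(s)
        assert fit.pH0 == pytest.approx(truth[0], rel=1e-3)
        assert fit.k == pytest.approx(truth[1], rel=1e-3)
        assert diag.rmse <= 1e-8

    def test_ph_rate_ratio_across_conditions(self):
        """The humid condition's pH decay is about 5.5x the dry one's."""
        fits = {}
        for erh, truth in PH_ROWS:
            s = gen_kinetic_series(ExponentialDecayParams(*truth),
                                   np.linspace(0, 3.0, 13), 0.0, 1, 0,
                                   "ph", str(erh))[0]
            fits[erh], _ = fit_exp_decay(s)
        assert fits[65].k / fits[11].k == pytest.approx(2.11 / 0.38, rel=1e-3)

    def test_flat_series_unidentifiable(self):
        s = KineticSeries(times=np.arange(5.0), values=np.full(5, 3.5),
                          response_kind="moisture")
        with pytest.raises(FitError, match="unidentifiable"):
            fit_asymptotic_first_order(s)

    def test_too_few_points_rejected(self):
        s = KineticSeries(times=[0.0, 1, 2], values=[3.5, 4, 4.2],
                          response_kind="moisture")
        with pytest.raises(DomainError):
            fit_asymptotic_first_order(s)
        s2 = KineticSeries(times=[0.0, 1], values=[5.0, 4.9],
                           response_kind="ph")
        with pytest.raises(DomainError):
            fit_exp_decay(s2)

    def test_recovery_unbiased_at_study_noise_scale(self):
        """Mean recovered uptake rate over many noisy replicates sits within
        Monte-Carlo error of the generating value (65% ERH conditions)."""
        truth = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        t = np.arange(0, 31)
        ks = []
        for seed in range(200):
            s = gen_kinetic_series(truth, t, 0.11, 1, seed, "moisture", "65")[0]
            fit, _ = fit_asymptotic_first_order(s)
            ks.append(fit.k)
        ks = np.asarray(ks)
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 0.15) < 4 * se + 1e-4


class TestTimeToLevel:
    def test_level_equal_start_is_zero(self):
        p = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        assert time_to_level_asymptotic(p, 3.3) == 0.0

    def test_monolayer_crossing_time(self):
        p = AsymptoticFirstOrderParams(3.3, 14.7, 0.15)
        t = time_to_level_asymptotic(p, 6.22)
        assert t == pytest.approx(1.9727, abs=1e-3)
        assert asymptotic_first_order(p, t) == pytest.approx(6.22, abs=1e-10)

    def test_decreasing_series_cannot_rise(self):
        p = AsymptoticFirstOrderParams(3.5, 2.8, 0.08)
        with pytest.raises(NeverReachedError):
            time_to_level_asymptotic(p, 5.0)

    def test_closed_form_agrees_with_numeric_root(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            y0, yinf = sorted(rng.uniform(0, 20, 2))
            if rng.random() < 0.5:
                y0, yinf = yinf, y0
            p = AsymptoticFirstOrderParams(y0, yinf, rng.uniform(0.01, 2.0))
            level = y0 + rng.uniform(0.05, 0.95) * (yinf - y0)
            t = time_to_level_asymptotic(p, level)
            t_num = brentq(lambda tt: asymptotic_first_order(p, tt) - level,
                           0.0, 1e4, xtol=1e-12)
            assert t == pytest.approx(t_num, abs=1e-8)

    def test_decay_closed_form(self):
        p = ExponentialDecayParams(5.08, 2.11e-4)
        assert time_to_level_decay(p, 5.0) == pytest.approx(75.23, abs=0.01)
        assert time_to_level_decay(ExponentialDecayParams(np.e, 1.0),
                                   1.0) == pytest.approx(1.0, rel=1e-12)

    def test_decay_level_above_start_warns_and_returns_zero(self):
        p = ExponentialDecayParams(5.07, 1e-4)
        with pytest.warns(UserWarning):
            assert time_to_level_decay(p, 5.1) == 0.0

    def test_zero_rate_never_reaches(self):
        with pytest.raises(NeverReachedError):
            time_to_level_decay(ExponentialDecayParams(5.07, 0.0), 5.0)


class TestSeriesValidation:
    def test_ph_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            KineticSeries(times=[0.0, 1], values=[5.0, 15.0], response_kind="ph")

    def test_wrong_time_unit_rejected(self):
        with pytest.raises(UnitError):
            KineticSeries(times=[0.0, 1], values=[5.0, 4.9],
                          response_kind="ph", time_unit="seconds")

    def test_mixed_units_in_csv_rejected(self, tmp_path):
        p = tmp_path / "k.csv"
        p.write_text("time,value,unit,response,erh,replicate\n"
                     "0,3.5,days,moisture,65,r1\n"
                     "1,3.9,seconds,moisture,65,r1\n")
        with pytest.raises(UnitError):
            read_kinetics_csv(p)

    def test_tidy_csv_round_trip(self, tmp_path):
        p = tmp_path / "k.csv"
        p.write_text("time,value,unit,response,erh,replicate\n"
                     "0,3.5,days,moisture,65,r1\n"
                     "1,4.9,days,moisture,65,r1\n"
                     "0,3.4,days,moisture,65,r2\n"
                     "1,5.0,days,moisture,65,r2\n")
        series = read_kinetics_csv(p)
        assert len(series) == 2
        assert all(s.condition == "65" for s in series)
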