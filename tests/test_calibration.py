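"""Transparency calibration chain: power law, exponent averaging, duration fit."""

import numpy as np
import pandas as pd
import pytest

from pteroshell import GeneratorConfig, TransparencyCalibrator, generate_transparency_dataset
from pteroshell.calibration import (
    CalibrationError,
    CalibrationModel,
    alpha_from_day0,
    average_exponent,
    fit_duration_effect,
    fit_power_per_season,
    predict_d4t,
)


class TestPowerFit:
    def test_noiseless_exact_recovery(self):
        omega = np.array([0.6, 0.8, 1.0, 1.3, 1.7])
        t = 0.7 * omega**0.255
        alpha, b = fit_power_per_season(omega, t)
        assert alpha == pytest.approx(0.700, abs=1e-6)
        assert b == pytest.approx(0.255, abs=1e-6)

    def test_nls_matches_on_noiseless_data(self):
        omega = np.array([0.6, 0.8, 1.0, 1.3, 1.7])
        t = 0.7 * omega**0.255
        alpha, b = fit_power_per_season(omega, t, method="nls")
        assert (alpha, b) == pytest.approx((0.7, 0.255), abs=1e-6)

    def test_degenerate_omega_spread_errors(self):
        with pytest.raises(CalibrationError):
            fit_power_per_season(np.full(5, 1.2), np.linspace(0.6, 0.8, 5))

    def test_scale_consistency(self):
        rng = np.random.default_rng(0)
        omega = rng.uniform(0.6, 1.7, 20)
        t = 0.7 * omega**0.255 * np.exp(rng.normal(0, 0.03, 20))
        a1, b1 = fit_power_per_season(omega, t)
        a2, b2 = fit_power_per_season(omega, 1.7 * t)
        assert a2 == pytest.approx(1.7 * a1, rel=1e-9)
        assert b2 == pytest.approx(b1, abs=1e-12)

    def test_simulation_recovery_of_exponent(self):
        """Mean recovered exponent over noisy seasons sits on the truth."""
        rng = np.random.default_rng(42)
        bs = []
        for _ in range(200):
            omega = rng.uniform(0.6, 1.7, 21)
            t = 0.7 * omega**0.255 + rng.normal(0, 0.03, 21)
            bs.append(fit_power_per_season(omega, t)[1])
        bs = np.asarray(bs)
        se = bs.std(ddof=1)
        assert bs.mean() == pytest.approx(0.255, abs=2 * se)


class TestExponentAveraging:
    def test_two_values(self):
        assert average_exponent([0.2, 0.3]) == pytest.approx((0.25, 0.05))

    def test_equal_values_zero_se(self):
        assert average_exponent([0.255] * 5)[1] == 0.0

    def test_se_scaling_matches_sampling_sd(self):
        # SE = sigma / sqrt(5): five draws from N(0.255, 0.072^2)
        rng = np.random.default_rng(3)
        ses = [average_exponent(rng.normal(0.255, 0.072, 5))[1] for _ in range(4000)]
        assert np.mean(ses) == pytest.approx(0.072 / np.sqrt(5), abs=0.004)

    def test_single_season_rejected(self):
        with pytest.raises(CalibrationError):
            average_exponent([0.255])


class TestAlphaLine:
    def test_pristine_shell_value(self):
        assert alpha_from_day0(0.90) == pytest.approx(0.8177, abs=1e-4)
        assert round(alpha_from_day0(0.90), 2) == 0.82

    def test_root_of_line_is_zero(self):
        assert alpha_from_day0(0.1087 / 1.0293) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        assert alpha_from_day0(0.63) == pytest.approx(0.5398, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(CalibrationError):
            alpha_from_day0(0.05)


class TestD4T:
    def test_unit_saturation_returns_alpha(self):
        assert predict_d4t(1.0, 0.77) == pytest.approx(0.77)

    @pytest.mark.parametrize(
        "omega,expected", [(1.5, 0.9093), (0.63, 0.7289)]
    )
    def test_hand_arithmetic(self, omega, expected):
        assert predict_d4t(omega, 0.82) == pytest.approx(expected, abs=1e-4)


class TestDurationFit:
    def make_records(self, slope=-0.0238, beta=0.1026, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for treatment, omega0 in [("medium", 1.0), ("high", 0.7)]:
            for d in (1.5, 4.0, 8.0, 15.0):
                for _ in range(7):
                    omega = omega0 + rng.uniform(-0.05, 0.05)
                    d4t = 0.75 * omega**0.255
                    t = d4t + slope * d + beta + rng.normal(0, noise)
                    rows.append(
                        dict(season="Nov14", treatment=treatment, omega_ar=omega,
                             duration_days=d, transparency=t)
                    )
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self):
        rec = self.make_records()
        slope, beta = fit_duration_effect(rec, {"Nov14": 0.75}, floor=None)
        assert slope == pytest.approx(-0.0238, abs=1e-9)
        assert beta == pytest.approx(0.1026, abs=1e-9)

    def test_ambient_only_input_errors(self):
        rec = self.make_records()
        rec["treatment"] = "ambient"
        with pytest.raises(CalibrationError):
            fit_duration_effect(rec, {"Nov14": 0.75})

    def test_single_duration_errors(self):
        rec = self.make_records()
        rec = rec[rec.duration_days == 4.0]
        with pytest.raises(CalibrationError):
            fit_duration_effect(rec, {"Nov14": 0.75})

    def test_noisy_recovery_within_two_se(self):
        slopes = [
            fit_duration_effect(
                self.make_records(noise=0.03, seed=s), {"Nov14": 0.75}, floor=None
            )[0]
            for s in range(200)
        ]
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1)
        assert slopes.mean() == pytest.approx(-0.0238, abs=2 * se)


class TestCalibratorEstimator:
    def test_full_chain_on_synthetic_data(self):
        df = generate_transparency_dataset(GeneratorConfig(seed=21))
        cal = TransparencyCalibrator().fit(df)
        assert set(cal.alpha_by_season_) == set(df["season"].unique())
        assert cal.exponent_b_ > 0
        assert cal.duration_slope_ < 0
        # fitted alphas track the generating alphas
        truth = df.groupby("season")["true_alpha"].first()
        for season, alpha in cal.alpha_by_season_.items():
            assert alpha == pytest.approx(truth[season], abs=0.05)

    def test_chain_recovers_constants_within_two_se(self):
        """Replicated synthetic seasons recover the generating exponent and
        duration slope (SE taken as the replicate SD)."""
        bs, slopes = [], []
        for seed in range(40):
            df = generate_transparency_dataset(GeneratorConfig(seed=seed))
            cal = TransparencyCalibrator().fit(df)
            bs.append(cal.exponent_b_)
            slopes.append(cal.duration_slope_)
        bs, slopes = np.asarray(bs), np.asarray(slopes)
        assert bs.mean() == pytest.approx(0.255, abs=2 * bs.std(ddof=1))
        assert slopes.mean() == pytest.approx(
            -0.0238, abs=2 * slopes.std(ddof=1)
        )

    def test_seasonal_exponent_spread_consistent_with_noise(self):
        """Per-season exponents share a common value: their spread matches
        the fitted SE, with no season-specific exponent shift."""
        df = generate_transparency_dataset(GeneratorConfig(seed=77))
        cal = TransparencyCalibrator().fit(df)
        exps = np.array(list(cal.exponents_by_season_.values()))
        # all seasons within 3 cross-season SDs of the mean
        assert np.all(np.abs(exps - exps.mean()) < 3 * exps.std(ddof=1) + 1e-12)

    def test_predict_matches_model_structure(self):
        df = generate_transparency_dataset(GeneratorConfig(seed=4, noise_sd_transparency=0.0))
        cal = TransparencyCalibrator().fit(df)
        pred = cal.predict(df)
        resid = df["transparency"] - pred
        assert np.abs(resid[~np.isclose(df["transparency"], 0.40)]).max() < 0.02

    def test_model_json_round_trip(self, tmp_path):
        df = generate_transparency_dataset(GeneratorConfig(seed=2))
        cal = TransparencyCalibrator().fit(df)
        path = tmp_path / "model.json"
        cal.model_.to_json(path)
        back = CalibrationModel.from_json(path)
        assert back == cal.model_

    def test_sklearn_params_round_trip(self):
        cal = TransparencyCalibrator(fit_method="nls")
        assert cal.get_params()["fit_method"] == "nls"
        cal.set_params(fit_method="loglog")
        assert cal.fit_method == "loglog"

    def test_missing_day4_errors(self):
        df = generate_transparency_dataset(GeneratorConfig(seed=2))
        with pytest.raises(CalibrationError):
            TransparencyCalibrator(day4_duration=99.0).fit(df)
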