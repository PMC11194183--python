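"""Exposure inversion: intensity, duration, emergence, envelopes."""

import numpy as np
import pytest

from pteroshell.inversion import (
    DURATION_FLOOR_DAYS,
    InversionDomainError,
    emergence_time,
    exposure_envelope,
    forward_transparency,
    invert_duration,
    invert_omega,
)
from pteroshell.profiles import PROFILES, TransparencyConstants, get_profile


class TestInvertOmega:
    def test_unit_saturation_fixed_point(self):
        # numerator equals alpha=0.81 -> omega exactly 1
        assert invert_omega(0.7756, 0.0, "eq5_verbatim") == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        expected = 10 ** (np.log10((0.70 + 0.0952 + 0.0344) / 0.81) / 0.255)
        assert invert_omega(0.70, 4.0, "eq5_verbatim") == pytest.approx(expected)

    def test_forward_inverse_round_trip(self):
        for profile in ("eq5_verbatim", "self_consistent"):
            for omega in (0.6, 0.9, 1.2, 1.5):
                for d in (0.0, 2.5, 8.0):
                    t = forward_transparency(omega, d, profile)
                    assert invert_omega(t, d, profile) == pytest.approx(
                        omega, abs=1e-6
                    )

    def test_nonpositive_argument_rejected(self):
        # with beta = 0.1026 a tiny transparency at zero duration leaves a
        # non-positive power-law term
        with pytest.raises(InversionDomainError):
            invert_omega(0.01, 0.0, "results_text")


class TestInvertDuration:
    def test_zero_deficit_point(self):
        c = get_profile("eq6_verbatim")
        t = c.alpha_pristine * 1.1**c.exponent_b + c.beta
        res = invert_duration(t, 1.1, "eq6_verbatim")
        assert res.days == pytest.approx(0.0, abs=1e-12)
        assert not res.below_emergence

    def test_verbatim_constants_at_unit_omega(self):
        assert invert_duration(0.8755, 1.0, "eq6_verbatim").days == pytest.approx(
            0.0, abs=1e-12
        )

    def test_pristine_day4_prediction_gives_emergence_offset(self):
        # T equal to the pristine Day-4 prediction alpha * omega^e
        c = get_profile("eq6_verbatim")
        t = c.alpha_pristine * 1.0**c.exponent_b
        res = invert_duration(t, 1.0, "eq6_verbatim")
        assert res.days == pytest.approx(0.0555 / 0.0239, abs=1e-9)
        assert res.days == pytest.approx(2.32, abs=0.005)

    def test_negative_duration_flagged_not_clamped(self):
        res = invert_duration(0.95, 1.4, "eq6_verbatim")
        assert res.days < 0
        assert res.below_emergence

    def test_invalid_omega_rejected(self):
        with pytest.raises(InversionDomainError):
            invert_duration(0.7, 0.0)


class TestEmergenceTime:
    def test_verbatim_duration_constants(self):
        assert emergence_time("eq6_verbatim") == pytest.approx(
            0.0555 / 0.0239
        )
        assert round(emergence_time("eq6_verbatim"), 1) == 2.3

    def test_results_text_profile_documents_inconsistency(self):
        # the results-narrative constants put emergence at 4.31 d instead
        assert emergence_time("results_text") == pytest.approx(4.31, abs=0.005)

    def test_zero_slope_limit_undefined(self):
        degenerate = TransparencyConstants("flat", 0.82, 0.255, 0.0, 0.1)
        assert emergence_time(degenerate) == np.inf


class TestExposureEnvelope:
    def test_curve_monotone_increasing_in_omega(self):
        env = exposure_envelope(0.6)
        assert (env.curve["omega_ar"].diff().dropna() > 0).all()
        assert (env.curve["duration_days"].diff().dropna() > 0).all()

    def test_monotonicity_matches_analytic_derivative_sign(self):
        # dD/dOmega = -alpha * b * Omega^(b-1) / slope > 0 for slope < 0
        c = get_profile("eq6_verbatim")
        omega = np.linspace(0.5, 1.5, 50)
        deriv = -c.alpha_pristine * c.exponent_b * omega ** (c.exponent_b - 1) / (
            c.duration_slope
        )
        assert (deriv > 0).all()

    def test_severity_ordering_curves_never_cross(self):
        grid = np.arange(0.5, 1.51, 0.01)
        envelopes = {
            t: exposure_envelope(t, omega_grid=grid) for t in (0.5, 0.7, 0.9)
        }
        merged = envelopes[0.7].curve.merge(
            envelopes[0.9].curve, on="omega_ar", suffixes=("_70", "_90")
        )
        assert (merged["duration_days_90"] < merged["duration_days_70"]).all()
        merged = envelopes[0.5].curve.merge(
            envelopes[0.7].curve, on="omega_ar", suffixes=("_50", "_70")
        )
        assert (merged["duration_days_70"] < merged["duration_days_50"]).all()

    def test_duration_floor_respected(self):
        env = exposure_envelope(0.7)
        assert (env.curve["duration_days"] >= DURATION_FLOOR_DAYS).all()
        assert env.curve["omega_ar"].max() <= 1.5

    def test_endpoint_arithmetic(self):
        c = get_profile("eq6_verbatim")
        with pytest.warns(UserWarning):
            env = exposure_envelope(0.4, omega_grid=np.array([1.5]))
        expected = (0.4 - 0.82 * 1.5**c.exponent_b - 0.0555) / (-0.0239)
        assert env.curve["duration_days"].iloc[0] == pytest.approx(expected)

    def test_out_of_range_transparency_warns_but_produces_curve(self):
        with pytest.warns(UserWarning):
            env = exposure_envelope(0.35)
        assert len(env.curve) > 0
        assert env.out_of_observed_range

    def test_near_pristine_shell_has_empty_envelope(self):
        # a nearly pristine shell implies sub-emergence exposure everywhere
        with pytest.warns(UserWarning):
            env = exposure_envelope(0.95)
        assert len(env.curve) == 0

    def test_below_observed_floor_flagged(self):
        with pytest.warns(UserWarning):
            env = exposure_envelope(0.42)
        assert env.below_transparency_floor


class TestProfiles:
    def test_unknown_profile_rejected(self):
        with pytest.raises(KeyError):
            get_profile("nope")

    def test_verbatim_constant_sets_preserved(self):
        eq5 = PROFILES["eq5_verbatim"]
        eq6 = PROFILES["eq6_verbatim"]
        assert (eq5.alpha_pristine, eq5.duration_slope, eq5.beta) == (
            0.81, -0.0238, -0.0344,
        )
        assert (eq6.alpha_pristine, eq6.exponent_b, eq6.duration_slope, eq6.beta) == (
            0.82, 0.0255, -0.0239, 0.0555,
        )
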