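"""FCS triplet model: closed forms, normalization, fitting, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipscreen.exceptions import InvalidInputError
from chipscreen.fcs import (
    FcsCurve,
    FcsInstrument,
    FcsParams,
    TripletModel,
    autocorrelation,
    calibrate_confocal_volume,
    diffusivity_from_tau,
    fit_fcs,
    normalize_curve,
)
from chipscreen.synthetic import make_fcs_curve

LAGS = np.logspace(-7, -3, 50)
TRUE = FcsParams(n_particles=1.0, tau_d=2.35e-5, p=0.2, triplet_amp=0.15, tau_t=2e-6)


class TestAutocorrelation:
    def test_zero_lag_without_triplet(self):
        params = FcsParams(10.0, 1e-4, 0.2)
        assert autocorrelation(0.0, params) == pytest.approx(0.100, rel=1e-12)

    def test_zero_lag_with_triplet(self):
        params = FcsParams(10.0, 1e-4, 0.2, triplet_amp=0.25, tau_t=1e-6)
        assert autocorrelation(0.0, params) == pytest.approx(1.0 / (10.0 * 0.75), rel=1e-12)

    def test_long_lag_decays_to_zero(self):
        params = FcsParams(1.0, 1e-5, 0.2, 0.1, 1e-6)
        assert autocorrelation(10.0, params) < 1e-6

    @given(
        tau_d=st.floats(1e-6, 1e-3),
        n=st.floats(0.1, 100.0),
        t_amp=st.floats(0.0, 0.5),
    )
    def test_strictly_decreasing(self, tau_d, n, t_amp):
        params = FcsParams(n, tau_d, 0.2, t_amp, tau_d / 20)
        g = autocorrelation(np.logspace(-8, -1, 40), params)
        assert np.all(np.diff(g) < 0)

    def test_paper_literal_p_variant_differs(self):
        params = FcsParams(1.0, 1e-5, 0.3)
        tau = 1e-5
        standard = autocorrelation(tau, params, p_squared=True)
        literal = autocorrelation(tau, params, p_squared=False)
        assert standard != pytest.approx(literal)
        # p < 1 makes the literal axial term decay faster
        assert literal < standard

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            FcsParams(1.0, 1e-5, 0.2, triplet_amp=1.0)


class TestNormalizeCurve:
    def test_first_element_is_one(self):
        curve, _ = make_fcs_curve(TRUE, LAGS, noise_frac=0.0)
        assert normalize_curve(curve).g[0] == pytest.approx(1.0)

    def test_constant_curve_all_ones(self):
        curve = FcsCurve(LAGS, np.full(LAGS.size, 0.37))
        assert np.allclose(normalize_curve(curve).g, 1.0)

    def test_amplitude_cancels(self):
        few = FcsParams(0.5, TRUE.tau_d, TRUE.p, TRUE.triplet_amp, TRUE.tau_t)
        many = FcsParams(50.0, TRUE.tau_d, TRUE.p, TRUE.triplet_amp, TRUE.tau_t)
        g_few = normalize_curve(make_fcs_curve(few, LAGS)[0]).g
        g_many = normalize_curve(make_fcs_curve(many, LAGS)[0]).g
        assert np.allclose(g_few, g_many, rtol=1e-12)


class TestFit:
    def test_noiseless_round_trip_all_free(self):
        curve, _ = make_fcs_curve(TRUE, LAGS, noise_frac=0.0)
        init = FcsParams(0.7, 8e-6, 0.3, 0.05, 1e-6)
        results = fit_fcs(curve, init)
        for name in ("n_particles", "tau_d", "p", "triplet_amp", "tau_t"):
            assert getattr(results.params, name) == pytest.approx(
                getattr(TRUE, name), rel=1e-3
            )

    def test_triplet_free_matches_pure_diffusion_when_t_zero(self):
        pure = FcsParams(2.0, 5e-5, 0.25)
        curve, _ = make_fcs_curve(pure, LAGS, noise_frac=0.0)
        fixed_off = fit_fcs(curve, FcsParams(1.0, 1e-5, 0.25, 0.0, 1e-6),
                            fixed=("triplet_amp", "tau_t", "p"))
        assert fixed_off.params.tau_d == pytest.approx(pure.tau_d, rel=1e-6)
        assert fixed_off.params.triplet_amp == 0.0

    def test_recovery_under_noise(self):
        errors = []
        for seed in range(30):
            curve, _ = make_fcs_curve(TRUE, LAGS, noise_frac=0.02, seed=seed)
            res = fit_fcs(curve, FcsParams(1.5, 1e-5, 0.2, 0.05, 1e-6), fixed=("p",))
            errors.append(abs(res.params.tau_d - TRUE.tau_d) / TRUE.tau_d)
        assert np.median(errors) < 0.05

    def test_fitted_params_respect_invariants(self):
        curve, _ = make_fcs_curve(TRUE, LAGS, noise_frac=0.10, seed=7)
        res = fit_fcs(curve, FcsParams(1.0, 1e-5, 0.2, 0.05, 1e-6), fixed=("p",))
        assert res.params.n_particles > 0
        assert 0.0 <= res.params.triplet_amp < 1.0

    def test_too_few_points_rejected(self):
        curve = FcsCurve(np.logspace(-6, -3, 5), np.linspace(1, 0.1, 5))
        with pytest.raises(InvalidInputError):
            TripletModel(curve)

    def test_narrow_lag_span_rejected(self):
        lags = np.linspace(1e-5, 2e-5, 20)
        with pytest.raises(InvalidInputError):
            TripletModel(FcsCurve(lags, np.linspace(1, 0.5, 20)))

    def test_summary_mentions_parameters(self):
        curve, _ = make_fcs_curve(TRUE, LAGS, noise_frac=0.0)
        res = fit_fcs(curve, TRUE)
        text = res.summary()
        assert "tau_d" in text and "R^2" in text


class TestDiffusivityCalibration:
    def test_known_conversion(self):
        instrument = FcsInstrument(r0=2.0e-7, z0=1.0e-6)
        assert diffusivity_from_tau(instrument, 2.35e-5) == pytest.approx(
            4.26e-10, rel=2e-3
        )

    def test_r0_scaling(self):
        small = diffusivity_from_tau(FcsInstrument(1e-7, 1e-6), 1e-5)
        big = diffusivity_from_tau(FcsInstrument(2e-7, 1e-6), 1e-5)
        assert big == pytest.approx(4 * small, rel=1e-12)

    def test_calibration_inverts_conversion(self):
        assert calibrate_confocal_volume(4.26e-10, 2.35e-5) == pytest.approx(
            2.0e-7, rel=2e-3
        )

    @given(d=st.floats(1e-12, 1e-8), tau=st.floats(1e-6, 1e-3))
    def test_round_trip_identity(self, d, tau):
        r0 = calibrate_confocal_volume(d, tau)
        instrument = FcsInstrument(r0=r0, z0=5 * r0)
        assert diffusivity_from_tau(instrument, tau) == pytest.approx(d, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            diffusivity_from_tau(FcsInstrument(1e-7, 1e-6), 0.0)
        with pytest.raises(InvalidInputError):
            calibrate_confocal_volume(-1e-10, 1e-5)
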