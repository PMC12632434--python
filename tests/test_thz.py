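"""ATR optics, spectral decomposition, lifetimes and Arrhenius analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesohydra import thz
from mesohydra.synthetic import DEFAULT_MODE_TRUTHS, ModeTruth, gen_thz_series
from mesohydra.thz import (
    DEFAULT_BACKGROUND,
    GAS_CONSTANT,
    SPEED_OF_LIGHT_CM_S,
    AbsorptionSpectrum,
    DHOMode,
    RawATRSpectrum,
    SpectralModel,
    WaterSpectrum,
)

NU = np.arange(50.0, 551.0, 2.0)


def default_model(**overrides):
    kw = dict(a_LF=150.0, a_HF=6000.0,
              stretching=DHOMode(1800.0, 147.0, 190.0),
              libration=DHOMode(3800.0, 412.0, 280.0))
    kw.update(overrides)
    return SpectralModel(**kw)


class TestPenetrationThickness:
    def test_hand_arithmetic_at_100_wavenumbers(self):
        # sqrt(2.42^2/2 - 1.47^2) = 0.87596; 100 um / (2 pi 0.87596)
        d = thz.penetration_thickness(100.0, 2.42, 1.47, math.pi / 4)
        assert d == pytest.approx(18.169272252834837, rel=1e-12)

    def test_wavelength_proportionality(self):
        assert (thz.penetration_thickness(200.0)
                / thz.penetration_thickness(100.0)) == pytest.approx(0.5, rel=1e-12)

    def test_no_evanescent_regime_raises(self):
        n_c, theta = 2.42, math.pi / 4
        with pytest.raises(ValueError):
            thz.penetration_thickness(100.0, n_c, n_c * math.sin(theta), theta)


class TestAbsorptionFromATR:
    def test_unit_transmission_gives_zero(self):
        raw = RawATRSpectrum(nu=NU, I0=np.ones_like(NU), I=np.ones_like(NU),
                             temperature=298.0)
        assert np.allclose(thz.absorption_from_atr(raw).alpha, 0.0)

    def test_single_decade_example(self):
        I0 = np.ones_like(NU)
        I = I0 * math.exp(-1.0)
        raw = RawATRSpectrum(nu=NU, I0=I0, I=I, temperature=298.0,
                             n_C=2.42, n_s=1.47)
        out = thz.absorption_from_atr(raw)
        k = np.argmin(np.abs(NU - 100.0))
        # alpha = 1 / d_s(100 cm^-1) = 1 / 18.169e-4 cm
        assert out.alpha[k] == pytest.approx(550.3797764073771, rel=1e-9)

    def test_round_trip_identity(self, rng):
        alpha_true = 100.0 + 300.0 * np.exp(-((NU - 200) ** 2) / (2 * 80**2))
        d_s_cm = thz.penetration_thickness(NU) * 1e-4
        I0 = np.full_like(NU, 2.0)
        raw = RawATRSpectrum(nu=NU, I0=I0, I=I0 * np.exp(-alpha_true * d_s_cm),
                             temperature=298.0)
        out = thz.absorption_from_atr(raw)
        assert np.allclose(out.alpha, alpha_true, rtol=1e-12)

    def test_decadic_rescales_by_ln10(self):
        I0 = np.ones_like(NU)
        raw = RawATRSpectrum(nu=NU, I0=I0, I=I0 * 0.5, temperature=298.0)
        nat = thz.absorption_from_atr(raw).alpha
        dec = thz.absorption_from_atr(raw, decadic=True).alpha
        assert np.allclose(nat, dec * math.log(10.0), rtol=1e-12)

    def test_transmission_above_incident_rejected(self):
        with pytest.raises(ValueError):
            RawATRSpectrum(nu=NU, I0=np.ones_like(NU), I=np.ones_like(NU) * 1.1,
                           temperature=298.0)


class TestSubtractLipid:
    def _spec(self, alpha, nu=NU):
        return AbsorptionSpectrum(nu=nu, alpha=alpha, temperature=298.0)

    def test_zero_fraction_is_identity(self):
        a = self._spec(np.linspace(1, 5, len(NU)))
        m = self._spec(np.linspace(2, 3, len(NU)))
        assert np.allclose(thz.subtract_lipid(a, m, 0.0).delta_alpha, a.alpha)

    def test_full_fraction_of_itself_vanishes(self):
        a = self._spec(np.linspace(1, 5, len(NU)))
        out = thz.subtract_lipid(a, a, 1.0)
        assert np.allclose(out.delta_alpha, 0.0)

    def test_half_fraction_linear_arithmetic(self):
        base = np.linspace(2, 6, len(NU))
        out = thz.subtract_lipid(self._spec(2 * base), self._spec(base), 0.5)
        assert np.allclose(out.delta_alpha, 1.5 * base, rtol=1e-12)

    def test_resampling_warns_and_interpolates(self):
        coarse = np.arange(48.0, 556.0, 4.0)
        a = self._spec(np.full_like(NU, 4.0))
        m = self._spec(np.full_like(coarse, 2.0), nu=coarse)
        with pytest.warns(UserWarning):
            out = thz.subtract_lipid(a, m, 0.5)
        assert np.allclose(out.delta_alpha, 3.0)

    def test_disjoint_grids_rejected(self):
        a = self._spec(np.ones(26), nu=np.arange(50.0, 101.0, 2.0))
        m = self._spec(np.ones(26), nu=np.arange(400.0, 451.0, 2.0))
        with pytest.raises(ValueError):
            thz.subtract_lipid(a, m, 0.5)


class TestLineShapes:
    def test_zero_amplitude_vanishes(self):
        assert np.allclose(thz.eval_dho(NU, 0.0, 147.0, 190.0), 0.0)

    @pytest.mark.parametrize("width", [50.0, 190.0, 700.0])
    def test_value_at_center_independent_of_width(self, width):
        # algebraic substitution: L(nu0) = a/(4 pi) for the adopted grouping
        a = 1234.5
        val = thz.eval_dho(np.array([147.0]), a, 147.0, width)[0]
        assert val == pytest.approx(a / (4 * math.pi), rel=1e-12)

    def test_low_frequency_quadratic_onset(self):
        v1 = thz.eval_dho(np.array([1e-3]), 100.0, 147.0, 190.0)[0]
        v2 = thz.eval_dho(np.array([2e-3]), 100.0, 147.0, 190.0)[0]
        assert v2 / v1 == pytest.approx(4.0, rel=1e-6)

    def test_background_zero_scales(self):
        assert np.allclose(thz.eval_background(NU, DEFAULT_BACKGROUND, 0.0, 0.0),
                           0.0)

    def test_debye_line_plateaus_at_a0(self):
        # omega0 << nu << nu0: alpha_LF -> a0 before the exponential roll-off
        from mesohydra.thz import BackgroundShapes, _eval_lf
        val = _eval_lf(np.array([50.0]), 2.0, 5000.0, 2.0)[0]
        assert val == pytest.approx(2.0, rel=5e-2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a_str=st.floats(0.0, 5000.0), a_lib=st.floats(0.0, 5000.0),
           a_lf=st.floats(0.0, 100.0), a_hf=st.floats(0.0, 8000.0))
    def test_model_nonnegative_for_nonnegative_amplitudes(self, a_str, a_lib,
                                                          a_lf, a_hf):
        model = default_model(a_LF=a_lf, a_HF=a_hf,
                              stretching=DHOMode(a_str, 147.0, 190.0),
                              libration=DHOMode(a_lib, 412.0, 280.0))
        assert np.all(thz.eval_model(NU, model) >= 0.0)


class TestFitModel:
    def test_noiseless_fixed_point(self):
        truth = default_model()
        ws = WaterSpectrum(nu=NU, delta_alpha=thz.eval_model(NU, truth),
                           temperature=298.0)
        fit = thz.fit_model(ws, truth)
        assert fit.success
        for name in ("stretching", "libration"):
            got, want = fit.model.modes[name], truth.modes[name]
            assert got.center == pytest.approx(want.center, rel=1e-6)
            assert got.width == pytest.approx(want.width, rel=1e-6)
            assert got.amplitude == pytest.approx(want.amplitude, rel=1e-6)

    def test_mode_order_precondition(self):
        with pytest.raises(ValueError):
            SpectralModel(a_LF=1.0, a_HF=1.0,
                          stretching=DHOMode(1.0, 420.0, 100.0),
                          libration=DHOMode(1.0, 150.0, 100.0))

    def test_insufficient_coverage_rejected(self):
        nu = np.arange(100.0, 400.0, 2.0)
        ws = WaterSpectrum(nu=nu, delta_alpha=np.ones_like(nu), temperature=298.0)
        with pytest.raises(ValueError):
            thz.fit_model(ws, default_model())

    def test_recovery_with_noise_and_offset_init(self):
        spectra, truth = gen_thz_series(T_grid=[298.0], noise_sd=0.01, seed=42)
        tw = truth.parameters["true_widths_cm1"]
        init = default_model(
            a_LF=165.0, a_HF=6600.0,
            stretching=DHOMode(1980.0, 147.0 * 1.1, 180.0),
            libration=DHOMode(4180.0, 412.0 * 1.1, 300.0))
        fit = thz.fit_model(spectra[0], init)
        assert fit.success
        assert fit.model.stretching.center == pytest.approx(147.0, abs=1.0)
        assert fit.model.libration.center == pytest.approx(412.0, abs=1.0)
        assert fit.model.stretching.width == pytest.approx(
            tw["stretching"][0], rel=0.02)
        assert fit.model.libration.width == pytest.approx(
            tw["libration"][0], rel=0.02)


class TestLifetimes:
    def test_reference_value_at_180_wavenumbers(self):
        model = default_model(stretching=DHOMode(1.0, 147.0, 180.0))
        lt = thz.lifetimes(model, 298.0)[0]
        assert lt.tau_fs == pytest.approx(185.31338622119557, rel=1e-12)
        assert not lt.outside_band

    def test_reciprocal_width_halves_lifetime(self):
        m1 = default_model(stretching=DHOMode(1.0, 147.0, 100.0))
        m2 = default_model(stretching=DHOMode(1.0, 147.0, 200.0))
        t1 = thz.lifetimes(m1, 298.0)[0].tau_fs
        t2 = thz.lifetimes(m2, 298.0)[0].tau_fs
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)

    def test_unit_identity_tau_omega_c(self):
        for width in (53.0, 180.0, 950.0):
            model = default_model(stretching=DHOMode(1.0, 147.0, width))
            lt = thz.lifetimes(model, 298.0)[0]
            assert lt.tau_fs * 1e-15 * width * SPEED_OF_LIGHT_CM_S == pytest.approx(
                1.0, rel=1e-12)

    def test_slow_mode_flagged_outside_band(self):
        model = default_model(stretching=DHOMode(1.0, 147.0, 53.0))
        lt = thz.lifetimes(model, 298.0)[0]
        assert lt.tau_fs == pytest.approx(629.3662173550039, rel=1e-9)
        assert lt.outside_band


class TestArrhenius:
    def test_constant_series_degenerate(self):
        fit = thz.arrhenius_fit(np.full(5, 7.0), np.linspace(300, 340, 5))
        assert fit.E_a_kJ_mol == 0.0
        assert fit.r_squared == 0.0
        assert fit.degenerate

    def test_exact_log_linear_data(self):
        T = np.arange(298.0, 341.0, 3.0)
        values = 100.0 * np.exp(3520.0 / (GAS_CONSTANT * T))
        fit = thz.arrhenius_fit(values, T)
        assert fit.E_a_kJ_mol == pytest.approx(3.520, abs=1e-9)
        assert fit.prefactor == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        T = np.arange(298.0, 341.0, 3.0)
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(50):
            values = 100.0 * np.exp(3520.0 / (GAS_CONSTANT * T))
            values = values * (1 + 0.01 * rng.standard_normal(T.shape))
            estimates.append(thz.arrhenius_fit(values, T).E_a_kJ_mol)
        assert np.mean(estimates) == pytest.approx(3.52, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            thz.arrhenius_fit([1.0, 2.0], [300.0, 310.0])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            thz.arrhenius_fit([1.0, -2.0, 3.0], [300.0, 310.0, 320.0])


class TestAnalyzeSeries:
    def test_single_temperature_skips_arrhenius(self):
        spectra, _ = gen_thz_series(T_grid=[298.0], noise_sd=0.0, seed=0)
        out = thz.analyze_series(spectra, default_model())
        assert out.arrhenius == {}
        assert "stretching" in out.skipped

    def test_default_series_recovers_activation_energies(self):
        spectra, truth = gen_thz_series(seed=3)
        init = default_model(
            a_LF=165.0, a_HF=6600.0,
            stretching=DHOMode(1980.0, 147.0 * 1.1, 180.0),
            libration=DHOMode(4180.0, 412.0 * 1.1, 300.0))
        out = thz.analyze_series(spectra, init)
        assert not out.failed_temperatures
        assert out.arrhenius["stretching"].E_a_kJ_mol == pytest.approx(3.5, rel=0.10)
        assert out.arrhenius["libration"].E_a_kJ_mol == pytest.approx(7.4, rel=0.10)
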