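"""Dispersion arithmetic, the two-site closed form vs its numerical oracle,
and exchange-parameter fitting."""

import numpy as np
import pytest

from nmrbind.cpmg import (
    DEFAULT_TAU_CP_MS,
    DispersionCurve,
    ExchangeParams,
    bloch_mcconnell_r2eff,
    carver_richards_r2eff,
    delta_r2_screen,
    dual_field_fit,
    r2eff_from_intensity,
)
from nmrbind.errors import AnalysisError, ScreenError
from nmrbind.synthetic import DispersionSpec, generate_dispersion


def params(pa=0.95, kex=1500.0, dw=3.0, r20=8.0):
    return ExchangeParams(pa=pa, kex=kex, dw_ppm=dw,
                          r20_per_field={500.0: r20, 800.0: r20})


class TestR2effFromIntensity:
    def test_equal_intensity_is_zero(self):
        assert r2eff_from_intensity(5.0, 5.0) == 0.0

    def test_one_e_folding_over_40ms(self):
        assert r2eff_from_intensity(np.exp(-1.0), 1.0, 0.040) == pytest.approx(25.0)

    def test_intensity_above_reference_negative_rate_retained(self):
        r = r2eff_from_intensity(1.01, 1.0, 0.040)
        assert r == pytest.approx(-np.log(1.01) / 0.040)
        assert r < 0

    def test_lost_peak_raises(self):
        with pytest.raises(ValueError):
            r2eff_from_intensity(0.0, 1.0)


class TestCarverRichards:
    def test_no_shift_difference_returns_r20(self):
        p = params(dw=0.0)
        taus = np.array(DEFAULT_TAU_CP_MS) / 1e3
        assert np.allclose(carver_richards_r2eff(p, taus, 500.0), 8.0)

    def test_single_state_returns_r20(self):
        p = ExchangeParams(pa=1.0, kex=1500.0, dw_ppm=3.0, r20_per_field={500.0: 8.0})
        assert carver_richards_r2eff(p, 0.01, 500.0) == 8.0

    def test_fast_pulsing_limit_approaches_r20(self):
        p = params()
        assert carver_richards_r2eff(p, 1e-6, 500.0) == pytest.approx(8.0, abs=0.05)

    def test_monotone_nonincreasing_in_pulsing_rate(self):
        p = params()
        taus = np.array(sorted(set(DEFAULT_TAU_CP_MS))) / 1e3
        r2 = carver_richards_r2eff(p, taus, 800.0)
        assert np.all(np.diff(r2) >= -1e-6)

    def test_dispersion_amplitude_larger_at_higher_field(self):
        p = params()
        amp = {}
        for f in (500.0, 800.0):
            r2 = carver_richards_r2eff(p, np.array([0.625e-3, 10e-3]), f)
            amp[f] = r2[1] - r2[0]
        assert amp[800.0] > amp[500.0]

    def test_matches_oracle_at_reference_point(self):
        p = params(pa=0.95, kex=1500.0, dw=3.0)
        a = carver_richards_r2eff(p, 0.010, 500.0)
        b = bloch_mcconnell_r2eff(p, 0.010, field_MHz=500.0)
        assert a == pytest.approx(b, abs=1e-8)

    def test_no_overflow_at_extreme_kex(self):
        p = params(kex=9e4, dw=5.0)
        r2 = carver_richards_r2eff(p, 0.010, 800.0)
        assert np.isfinite(r2)


class TestBlochMcConnellOracle:
    def test_no_exchange_contrast_returns_r20_exactly(self):
        assert bloch_mcconnell_r2eff(params(dw=0.0), 0.01, field_MHz=500.0) == 8.0

    def test_fast_exchange_limit(self):
        # kex >> dw: R2eff -> R20 + pa pb dw^2/kex at slow pulsing
        p = params(pa=0.9, kex=1e6, dw=2.0)
        dw_rad = 2 * np.pi * 2.0 * 500.0 * 0.10136767
        expected = 8.0 + 0.9 * 0.1 * dw_rad**2 / 1e6
        got = bloch_mcconnell_r2eff(p, 0.010, field_MHz=500.0)
        assert got == pytest.approx(expected, abs=0.02)

    def test_finite_train_mode_rounds_noninteger_echo_count(self):
        p = params()
        with pytest.warns(UserWarning, match="rounded"):
            bloch_mcconnell_r2eff(p, 0.714e-3, field_MHz=500.0, mode="finite")

    def test_oracle_equivalence_spot_grid(self):
        """Closed form vs Bloch-McConnell propagation within 0.05 s^-1."""
        worst = 0.0
        for pa in (0.9, 0.95, 0.99):
            for kex in (200.0, 1000.0, 4000.0):
                for dw in (0.5, 2.75, 5.0):
                    p = params(pa=pa, kex=kex, dw=dw)
                    for f in (500.0, 800.0):
                        for t_ms in (0.625, 1.67, 10.0):
                            a = carver_richards_r2eff(p, t_ms / 1e3, f)
                            b = bloch_mcconnell_r2eff(p, t_ms / 1e3, field_MHz=f)
                            worst = max(worst, abs(a - b))
        assert worst < 0.05


class TestDeltaR2Screen:
    def _curve(self, r2_by_tau):
        taus = list(r2_by_tau)
        return DispersionCurve(1, 500.0, taus, [r2_by_tau[t] for t in taus])

    def test_flat_curve_not_dynamic(self):
        c = self._curve({0.625: 8.0, 1.0: 8.0, 5.0: 8.0, 10.0: 8.0})
        s = delta_r2_screen(c)
        assert s.delta_R2 == 0.0 and not s.is_dynamic

    def test_above_threshold_dynamic(self):
        c = self._curve({0.625: 8.0, 1.0: 8.5, 5.0: 10.0, 10.0: 10.5})
        assert delta_r2_screen(c).is_dynamic

    def test_exactly_two_not_dynamic(self):
        c = self._curve({0.625: 8.0, 1.0: 8.5, 5.0: 9.5, 10.0: 10.0})
        s = delta_r2_screen(c)
        assert s.delta_R2 == pytest.approx(2.0) and not s.is_dynamic

    def test_duplicates_averaged(self):
        c = DispersionCurve(1, 500.0, [0.625, 0.625, 10.0], [7.0, 9.0, 11.0])
        assert delta_r2_screen(c).delta_R2 == pytest.approx(3.0)

    def test_missing_required_delay_raises(self):
        c = self._curve({1.0: 8.0, 5.0: 10.0, 2.0: 9.0, 3.33: 9.5})
        with pytest.raises(ScreenError):
            delta_r2_screen(c)


class TestDualFieldFit:
    def test_noiseless_recovery_within_1_percent(self):
        truth = ExchangeParams(pa=0.97, kex=1000.0, dw_ppm=2.5,
                               r20_per_field={500.0: 8.0, 800.0: 10.0})
        curves = generate_dispersion(DispersionSpec(truth={1: truth}, noise_sd=0.0, seed=0))
        fit = dual_field_fit(curves)
        assert fit.success
        assert fit.params.pa == pytest.approx(0.97, rel=0.01)
        assert fit.params.kex == pytest.approx(1000.0, rel=0.01)
        assert fit.params.dw_ppm == pytest.approx(2.5, rel=0.01)
        assert fit.params.r20_per_field[500.0] == pytest.approx(8.0, rel=0.01)
        assert fit.params.r20_per_field[800.0] == pytest.approx(10.0, rel=0.01)
        assert fit.degeneracy_warning == ""

    def test_noisy_kex_within_2sd(self):
        truth = ExchangeParams(pa=0.95, kex=1200.0, dw_ppm=3.0,
                               r20_per_field={500.0: 8.0, 800.0: 10.0})
        curves = generate_dispersion(DispersionSpec(truth={1: truth}, noise_sd=0.3, seed=5))
        fit = dual_field_fit(curves)
        sd = fit.stderr.get("log10_kex", float("nan"))
        if np.isfinite(sd):
            assert abs(np.log10(fit.params.kex) - np.log10(1200.0)) < 3.0 * sd + 0.05
        else:
            assert fit.params.kex == pytest.approx(1200.0, rel=0.25)

    def test_flat_curve_refused(self):
        truth = ExchangeParams(pa=0.95, kex=1500.0, dw_ppm=0.0,
                               r20_per_field={500.0: 8.0, 800.0: 10.0})
        curves = generate_dispersion(DispersionSpec(truth={1: truth}, noise_sd=0.0, seed=0))
        with pytest.raises(AnalysisError, match="no dispersion"):
            dual_field_fit(curves)

    def test_single_field_flags_degeneracy(self):
        truth = ExchangeParams(pa=0.97, kex=1000.0, dw_ppm=2.5,
                               r20_per_field={500.0: 8.0})
        curves = generate_dispersion(
            DispersionSpec(truth={1: truth}, fields=(500.0,), noise_sd=0.0, seed=0)
        )
        fit = dual_field_fit(curves)
        assert "unidentifiable" in fit.degeneracy_warning
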