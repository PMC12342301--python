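"""Morlet CWT/XWT/WTC spectral identities and significance machinery."""

import numpy as np
import pytest
from scipy.stats import chi2

from budwormsync.sediment import AnnualSeries
from budwormsync.wavelet import (
    MORLET_CDELTA,
    WaveletParams,
    ar1_coefficient,
    ar1_significance,
    ar1_surrogate,
    cwt_morlet,
    wtc,
    xwt,
)


def _sin(period, n=120, first_year=1900, phase=0.0):
    t = np.arange(n)
    return AnnualSeries(first_year, np.sin(2 * np.pi * (t - phase) / period))


class TestCwt:
    def test_period_scale_ratio_closed_form(self):
        p = WaveletParams(omega0=6.0)
        assert p.fourier_factor == pytest.approx(1.033, abs=5e-4)
        prod = cwt_morlet(_sin(32))
        np.testing.assert_allclose(prod.periods / prod.scales, p.fourier_factor)

    def test_scales_follow_powers_of_two_grid(self):
        prod = cwt_morlet(_sin(32))
        p = prod.params
        np.testing.assert_allclose(
            prod.scales, p.s0 * 2.0 ** (p.dj * np.arange(prod.scales.size))
        )

    def test_sinusoid_peaks_at_nearest_fourier_period(self):
        prod = cwt_morlet(_sin(32))
        mean_power = prod.power.mean(axis=1)
        nearest = prod.periods[np.argmin(np.abs(prod.periods - 32.0))]
        assert prod.periods[np.argmax(mean_power)] == nearest

    def test_power_scales_with_amplitude_squared_before_normalization(self):
        x = _sin(16)
        a = cwt_morlet(x)
        b = cwt_morlet(AnnualSeries(1900, 3.0 * x.values))
        # internal normalization removes amplitude; variance records it
        assert b.variance == pytest.approx(9.0 * a.variance)
        np.testing.assert_allclose(
            b.power * b.variance, 9.0 * a.power * a.variance, rtol=1e-9
        )

    def test_variance_reconstruction_within_ten_percent(self):
        prod = cwt_morlet(_sin(16))
        p = prod.params
        rec = (
            p.dj * p.dt / (MORLET_CDELTA * prod.data.size)
            * np.sum(prod.power / prod.scales[:, None])
        )
        assert rec == pytest.approx(1.0, abs=0.10)  # normalized variance is 1

    def test_zero_variance_and_short_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cwt_morlet(AnnualSeries(1900, np.ones(64)))
        with pytest.raises(ValueError, match="short"):
            cwt_morlet(AnnualSeries(1900, np.arange(16.0)))

    def test_coi_is_sqrt2_efolding_from_each_edge(self):
        prod = cwt_morlet(_sin(32))
        p = prod.params
        d = 10
        expect = p.fourier_factor / np.sqrt(2.0) * p.dt * d
        assert prod.coi[d] == pytest.approx(expect)
        assert prod.coi[-1 - d] == pytest.approx(expect)


class TestAr1Significance:
    def test_chi_square_quantile_constant(self):
        assert chi2.ppf(0.95, 2) / 2.0 == pytest.approx(2.9957, abs=5e-4)

    def test_white_noise_background_is_flat(self):
        rng = np.random.default_rng(0)
        prod = cwt_morlet(AnnualSeries(1900, rng.standard_normal(128)))
        ar1_significance(prod, a=0.0)
        np.testing.assert_allclose(
            prod.signif_level, chi2.ppf(0.95, 2) / 2.0, rtol=1e-12
        )

    def test_ar1_estimate_recovers_coefficient(self):
        rng = np.random.default_rng(1)
        x = ar1_surrogate(0.7, 4000, rng)
        assert ar1_coefficient(x) == pytest.approx(0.7, abs=0.05)

    def test_nonstationary_background_rejected(self):
        prod = cwt_morlet(_sin(32))
        with pytest.raises(ValueError, match="stationary"):
            ar1_significance(prod, a=1.0)


class TestXwt:
    def test_self_comparison_in_phase_everywhere(self):
        px = cwt_morlet(_sin(32))
        prod = xwt(px, px)
        assert np.abs(prod.phase[prod.power > 1e-6]).max() < 1e-10

    def test_sign_flip_gives_anti_phase(self):
        px = cwt_morlet(_sin(32))
        py = cwt_morlet(AnnualSeries(1900, -_sin(32).values))
        prod = xwt(px, py)
        strong = prod.power > 0.5 * prod.power.max()
        assert np.abs(np.abs(prod.phase[strong]) - np.pi).max() < 1e-8

    def test_sin_vs_cos_quarter_cycle_phase(self):
        t = np.arange(120)
        px = cwt_morlet(AnnualSeries(1900, np.sin(2 * np.pi * t / 32)))
        py = cwt_morlet(AnnualSeries(1900, np.cos(2 * np.pi * t / 32)))
        prod = xwt(px, py)
        i = np.argmin(np.abs(prod.periods - 32))
        inside = prod.inside_coi()[i]
        med = np.median(np.abs(prod.phase[i][inside]))
        assert med == pytest.approx(np.pi / 2, abs=0.1)

    def test_phase_antisymmetry(self):
        rng = np.random.default_rng(2)
        px = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        py = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        np.testing.assert_allclose(xwt(px, py).phase, -xwt(py, px).phase, atol=1e-12)

    def test_axis_mismatch_rejected(self):
        px = cwt_morlet(_sin(32, n=120))
        py = cwt_morlet(_sin(32, n=64))
        with pytest.raises(ValueError, match="axes"):
            xwt(px, py)


class TestWtc:
    def test_perfect_linear_relation_gives_unit_coherence(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(120).cumsum()
        px = cwt_morlet(AnnualSeries(1900, x))
        py = cwt_morlet(AnnualSeries(1900, 2.0 * x))
        prod = wtc(px, py, n_mc=100, seed=0)
        assert prod.power.min() > 1.0 - 1e-6

    def test_symmetry_in_argument_order(self):
        rng = np.random.default_rng(4)
        px = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        py = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        a = wtc(px, py, n_mc=100, seed=1)
        b = wtc(py, px, n_mc=100, seed=1)
        np.testing.assert_allclose(a.power, b.power, atol=1e-12)

    def test_quarter_period_lag_shows_high_band_with_half_pi_phase(self):
        px = cwt_morlet(_sin(32))
        py = cwt_morlet(_sin(32, phase=8))  # delayed by period/4
        prod = wtc(px, py, n_mc=100, seed=2)
        i = np.argmin(np.abs(prod.periods - 32))
        inside = prod.inside_coi()[i]
        assert np.median(prod.power[i][inside]) > 0.9
        assert np.median(np.abs(prod.phase[i][inside])) == pytest.approx(
            np.pi / 2, abs=0.2
        )

    def test_independent_white_noise_has_low_mean_coherence(self):
        rng = np.random.default_rng(5)
        px = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        py = cwt_morlet(AnnualSeries(1900, rng.standard_normal(120)))
        prod = wtc(px, py, n_mc=120, seed=3)
        inside = prod.inside_coi()
        assert prod.power[inside].mean() < 0.5
        frac = np.mean(prod.signif_ratio[inside] > 1.0)
        assert frac < 0.2

    def test_seed_required_and_small_mc_warned(self):
        px = cwt_morlet(_sin(32))
        with pytest.raises(ValueError, match="seed"):
            wtc(px, px, n_mc=100)
        with pytest.warns(UserWarning, match="n_mc"):
            wtc(px, px, n_mc=8, seed=0)
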