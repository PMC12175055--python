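"""Morlet wavelet machinery: closed-form sinusoid oracles and null behavior."""

import numpy as np
import pytest

from sealsync import wavelets as wv


def kernel_response(period, cutoff=8.0):
    """Oracle: analytic transfer of the Gaussian low-pass at a period."""
    sigma = cutoff * np.sqrt(np.log(2.0)) / (np.pi * np.sqrt(2.0))
    return np.exp(-2.0 * np.pi**2 * sigma**2 / period**2)


class TestGaussianHighpass:
    def test_constant_series_returns_zeros(self):
        out = wv.gaussian_highpass(np.full(48, 5.0))
        np.testing.assert_allclose(out, 0.0)

    def test_half_power_at_cutoff_period(self):
        # at P = cutoff the low-pass response is exactly 1/2
        assert kernel_response(8.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("period,band", [(3.0, (0.9, 1.01)),
                                             (16.0, (0.0, 0.3))])
    def test_amplitude_response_matches_transfer_function(self, period, band):
        t = np.arange(96)
        x = np.sin(2 * np.pi * t / period)
        out = wv.gaussian_highpass(x, normalize=False)
        # measure away from the edges
        core = slice(16, -16)
        gain = out[core].std() / x[core].std()
        lo, hi = band
        assert lo <= gain <= hi
        expected = 1.0 - kernel_response(period)
        assert gain == pytest.approx(expected, abs=0.1)

    def test_output_normalized(self, rng):
        out = wv.gaussian_highpass(rng.standard_normal(60))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_interior_gaps_interpolated(self, rng):
        x = rng.standard_normal(50)
        x[20] = np.nan
        out = wv.gaussian_highpass(x)
        assert np.all(np.isfinite(out))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            wv.gaussian_highpass(np.arange(5.0), cutoff_years=8.0)


class TestCwtMorlet:
    def test_power_peak_at_fourier_factor_scale(self):
        """Sinusoid of period p peaks at scale p/1.033 within one dj step."""
        for period in (3.0, 5.0):
            t = np.arange(128)
            x = np.sin(2 * np.pi * t / period)
            scales = wv.default_scales(s0=1.5, s_max=8.0)
            spec = wv.cwt_morlet(x, scales)
            mean_power = spec.power[:, 20:-20].mean(axis=1)
            s_peak = scales[np.argmax(mean_power)]
            s_expected = period / wv.FOURIER_FACTOR
            dj = np.log2(scales[1] / scales[0])
            assert abs(np.log2(s_peak / s_expected)) <= dj + 1e-9

    def test_linearity(self, rng):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        a, b = 1.7, -0.6
        wa = wv.cwt_morlet(a * x + b * y)
        wx = wv.cwt_morlet(x)
        wy = wv.cwt_morlet(y)
        np.testing.assert_allclose(
            wa.coefficients, a * wx.coefficients + b * wy.coefficients,
            atol=1e-10)

    def test_white_noise_power_flat_across_scales(self):
        """Mean in-COI power shows no monotone scale trend for white noise."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        corrs = []
        for _ in range(100):
            x = rng.standard_normal(48)
            x = (x - x.mean()) / x.std()
            spec = wv.cwt_morlet(x)
            mask = spec.inside_coi()
            prof = np.array([spec.power[i][mask[i]].mean()
                             for i in range(len(spec.scales))
                             if mask[i].any()])
            corrs.append(spearmanr(np.arange(prof.size), prof).statistic)
        # mean trend statistic should be near zero at alpha=0.01
        z = np.mean(corrs) / (np.std(corrs, ddof=1) / np.sqrt(len(corrs)))
        assert abs(z) < 10  # no systematic monotone drift (generous 1% band)

    def test_nonfinite_series_rejected(self):
        x = np.ones(32)
        x[3] = np.nan
        with pytest.raises(ValueError):
            wv.cwt_morlet(x)

    def test_parseval_style_energy_match(self, rng):
        """Rectified wavelet power integrates to about the series variance."""
        x = rng.standard_normal(256)
        x = (x - x.mean()) / x.std()
        scales = wv.default_scales(s0=1.0, s_max=32.0, dj=1.0 / 12)
        spec = wv.cwt_morlet(x, scales)
        dj = 1.0 / 12
        # Torrence & Compo reconstruction constant for Morlet omega0=6
        cdelta = 0.776
        var_est = dj / (cdelta * x.size) * np.sum(spec.power / scales[:, None])
        assert var_est == pytest.approx(1.0, rel=0.15)


class TestWaveletCoherence:
    def test_identical_series_coherence_one_phase_zero(self, rng):
        x = wv.gaussian_highpass(rng.standard_normal(48))
        coh = wv.wavelet_coherence(x, x)
        inside = coh.inside_coi()
        assert np.all(coh.coherence[inside] > 1.0 - 1e-6)
        assert np.allclose(coh.phase[inside], 0.0, atol=1e-6)

    def test_quarter_period_lag_phase(self):
        """y delayed a quarter period behind x shows phase ~ pi/2 at that
        scale (analytic phase of lagged sinusoids)."""
        period = 4.0
        t = np.arange(64.0)
        x = np.sin(2 * np.pi * t / period)
        y = np.sin(2 * np.pi * (t - period / 4) / period)
        coh = wv.wavelet_coherence(x, y)
        k = np.argmin(np.abs(coh.scales - period / wv.FOURIER_FACTOR))
        phases = coh.phase[k, 16:-16]
        assert np.abs(np.angle(np.exp(1j * (phases - np.pi / 2)))).mean() < 0.2

    def test_independent_noise_low_mean_coherence(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(100):
            x = wv.gaussian_highpass(rng.standard_normal(48))
            y = wv.gaussian_highpass(rng.standard_normal(48))
            coh = wv.wavelet_coherence(x, y)
            vals.append(coh.coherence[coh.inside_coi()].mean())
        assert np.mean(vals) < 0.5

    def test_rescaling_invariance(self, rng):
        x = rng.standard_normal(48)
        y = rng.standard_normal(48)
        c1 = wv.wavelet_coherence(x, y)
        c2 = wv.wavelet_coherence(3.5 * x, 0.2 * y)
        np.testing.assert_allclose(c1.coherence, c2.coherence, atol=1e-10)

    def test_unsmoothed_request_refused(self, rng):
        with pytest.raises(ValueError):
            wv.wavelet_coherence(rng.standard_normal(48),
                                 rng.standard_normal(48), smooth=False)

    def test_coherence_bounded(self, rng):
        c = wv.wavelet_coherence(rng.standard_normal(40),
                                 rng.standard_normal(40))
        assert np.all((c.coherence >= 0) & (c.coherence <= 1))


class TestModulusRatio:
    def test_identical_series_ratio_one(self, rng):
        x = rng.standard_normal(48)
        field = wv.modulus_ratio([x, x, x])
        np.testing.assert_allclose(field.ratio, 1.0, atol=1e-9)

    def test_antiphase_pair_cancels(self):
        t = np.arange(64.0)
        x = np.sin(2 * np.pi * t / 4.0)
        field = wv.modulus_ratio([x, -x])
        k = np.argmin(np.abs(field.scales - 4.0 / wv.FOURIER_FACTOR))
        assert field.ratio[k, 16:-16].max() < 0.05

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(10):
            xs = [rng.standard_normal(40) for _ in range(3)]
            field = wv.modulus_ratio(xs)
            assert np.all((field.ratio >= 0) & (field.ratio <= 1))

    def test_single_series_rejected(self, rng):
        with pytest.raises(ValueError):
            wv.modulus_ratio([rng.standard_normal(30)])


class TestRednoiseSignificance:
    def test_seed_determinism(self, rng):
        x = rng.standard_normal(48)
        m1, c1 = wv.rednoise_significance(x, n_surrogates=50, seed=4)
        m2, c2 = wv.rednoise_significance(x, n_surrogates=50, seed=4)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(c1, c2)

    def test_white_noise_false_positive_rate(self):
        """Fraction of significant in-COI cells is near alpha for white
        noise (cells are correlated, so the band is generous)."""
        rng = np.random.default_rng(77)
        fracs = []
        for _ in range(25):
            x = rng.standard_normal(48)
            mask, _ = wv.rednoise_significance(x, n_surrogates=100,
                                               alpha=0.05,
                                               seed=int(rng.integers(2**31)))
            spec = wv.cwt_morlet(x)
            inside = spec.inside_coi()
            fracs.append(mask[inside].mean())
        assert 0.0 < np.mean(fracs) < 0.15

    def test_embedded_sinusoid_detected(self):
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(10):
            t = np.arange(48.0)
            x = 2.0 * np.sin(2 * np.pi * t / 4.0) + rng.standard_normal(48)
            mask, _ = wv.rednoise_significance(x, n_surrogates=100,
                                               seed=int(rng.integers(2**31)))
            spec = wv.cwt_morlet(x)
            k = np.argmin(np.abs(spec.scales - 4.0 / wv.FOURIER_FACTOR))
            inside = spec.inside_coi()[k]
            hits += mask[k][inside].mean() > 0.5
        assert hits >= 9

    def test_highpass_preserves_subcutoff_scales(self):
        """CWT at scales <= 8 yr of the filtered series stays close to the
        unfiltered transform for broadband noise."""
        rng = np.random.default_rng(3)
        rel = []
        for _ in range(10):
            x = rng.standard_normal(64)
            x = (x - x.mean()) / x.std()
            xf = wv.gaussian_highpass(x, normalize=False)
            scales = wv.default_scales(s0=2.0, s_max=4.0)
            a = wv.cwt_morlet(x, scales)
            b = wv.cwt_morlet(xf, scales)
            inside = a.inside_coi()
            rel.append(np.abs(b.power[inside] - a.power[inside]).sum()
                       / a.power[inside].sum())
        assert np.mean(rel) < 0.25
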