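"""Multitaper PSD estimation and relative power."""

import numpy as np
import pytest

from sleepalpha.spectral import (PowerSpectrum, average_channels, dpss_tapers,
                                 multitaper_psd, relative_power,
                                 relative_power_spectrum)
from sleepalpha.types import LOW_ALPHA

FS = 512.0


def _uniform_spectrum(value=1.0):
    freqs = np.arange(0.0, 35.0001, 0.25)
    return PowerSpectrum(freqs=freqs, psd=np.full_like(freqs, value))


class TestDPSS:
    def test_orthonormality(self):
        tapers, _ = dpss_tapers(2048, 3, 5)
        gram = tapers @ tapers.T
        assert np.abs(gram - np.eye(5)).max() < 1e-8

    def test_concentration_ratios_high(self):
        _, ratios = dpss_tapers(2048, 3, 5)
        assert np.all(ratios > 0.9)

    def test_taper_count_bound(self):
        with pytest.raises(ValueError, match="2\\*nw-1"):
            dpss_tapers(2048, 3, 6)


class TestMultitaperPSD:
    def test_white_noise_parseval(self):
        """Integrated PSD recovers the signal variance within 5%."""
        rng = np.random.default_rng(11)
        epochs = rng.standard_normal((100, 2048))
        ps = multitaper_psd(epochs, FS)
        var = np.mean([np.var(e) for e in epochs])
        integral = np.trapezoid(ps.psd, ps.freqs)
        assert integral == pytest.approx(var, rel=0.05)

    def test_sinusoid_band_power(self):
        """A sinusoid of amplitude A carries band power A^2/2."""
        a = 3.0
        t = np.arange(2048 * 40) / FS
        x = a * np.sin(2 * np.pi * 10.0 * t)
        epochs = x.reshape(40, 2048)
        ps = multitaper_psd(epochs, FS)
        band = ps.band_power(8.0, 12.0)
        assert band == pytest.approx(a**2 / 2, rel=0.05)

    def test_zero_signal_gives_zero_psd(self):
        ps = multitaper_psd(np.zeros((3, 1024)), FS)
        assert np.all(ps.psd == 0)

    def test_scale_equivariance_and_relative_power_invariance(self):
        rng = np.random.default_rng(5)
        epochs = rng.standard_normal((20, 2048))
        ps1 = multitaper_psd(epochs, FS)
        ps2 = multitaper_psd(3.0 * epochs, FS)
        assert np.allclose(ps2.psd, 9.0 * ps1.psd, rtol=1e-10)
        assert relative_power(ps2, LOW_ALPHA) == pytest.approx(
            relative_power(ps1, LOW_ALPHA), rel=1e-12)

    def test_lower_variance_than_periodogram(self):
        """Averaging 5 eigenspectra beats the single-taper periodogram."""
        rng = np.random.default_rng(9)
        epochs = rng.standard_normal((60, 2048))
        mt = np.stack([multitaper_psd(e[None, :], FS).psd for e in epochs])
        pg = []
        for e in epochs:
            w = np.hanning(len(e))
            spec = np.abs(np.fft.rfft((e - e.mean()) * w)) ** 2
            pg.append(2 * spec / (FS * (w**2).sum()))
        pg = np.stack(pg)
        sel = slice(20, 100)  # interior frequencies
        ratio = (mt[:, sel].var(axis=0) / pg[:, sel].var(axis=0)).mean()
        assert ratio < 1.0

    def test_empty_epochs_rejected(self):
        with pytest.raises(ValueError):
            multitaper_psd(np.empty((0, 1024)), FS)


class TestAverageChannels:
    def test_idempotent_on_identical_inputs(self):
        ps = _uniform_spectrum(2.0)
        out = average_channels(ps, ps)
        assert np.allclose(out.psd, ps.psd)
        assert out.meta["channel"] == "FP-mean"

    def test_linearity(self):
        zero = _uniform_spectrum(0.0)
        ps = _uniform_spectrum(4.0)
        assert np.allclose(average_channels(zero, ps).psd, 2.0)

    def test_grid_mismatch_rejected(self):
        a = _uniform_spectrum()
        b = PowerSpectrum(freqs=np.arange(0, 30.0, 0.5),
                          psd=np.ones(60))
        with pytest.raises(ValueError, match="grid"):
            average_channels(a, b)


class TestRelativePower:
    def test_uniform_psd_gives_bandwidth_ratio(self):
        """LA band (1.5 Hz wide) over 0.5-30 (29.5 Hz) = 1.5/29.5."""
        ps = _uniform_spectrum()
        assert relative_power(ps, LOW_ALPHA) == pytest.approx(1.5 / 29.5,
                                                              abs=1e-12)

    def test_band_equals_total_gives_one(self):
        ps = _uniform_spectrum()
        assert relative_power(ps, (0.5, 30.0)) == pytest.approx(1.0)

    def test_all_power_inside_band(self):
        freqs = np.arange(0.0, 35.0001, 0.25)
        psd = np.where((freqs >= 7.25) & (freqs <= 8.25), 5.0, 0.0)
        ps = PowerSpectrum(freqs=freqs, psd=psd)
        assert relative_power(ps, LOW_ALPHA) == pytest.approx(1.0)

    def test_band_outside_total_rejected(self):
        with pytest.raises(ValueError, match="total"):
            relative_power(_uniform_spectrum(), (0.1, 5.0))

    def test_disjoint_contiguous_bands_are_additive(self):
        rng = np.random.default_rng(2)
        freqs = np.arange(0.0, 35.0001, 0.25)
        ps = PowerSpectrum(freqs=freqs, psd=rng.uniform(0.5, 2.0, len(freqs)))
        whole = relative_power(ps, (5.0, 15.0))
        parts = relative_power(ps, (5.0, 10.0)) + relative_power(ps, (10.0, 15.0))
        assert parts == pytest.approx(whole, rel=1e-12)


class TestRelativePowerSpectrum:
    def test_uniform_bins(self):
        centers, fracs = relative_power_spectrum(_uniform_spectrum())
        assert len(centers) == 50
        assert np.allclose(fracs, 0.5 / 29.5)

    def test_bins_tile_to_unity(self):
        rng = np.random.default_rng(4)
        freqs = np.arange(0.0, 35.0001, 0.25)
        ps = PowerSpectrum(freqs=freqs, psd=rng.uniform(0.5, 2.0, len(freqs)))
        _, fracs = relative_power_spectrum(ps, bin_range=(0.5, 30.0),
                                           total_band=(0.5, 30.0))
        assert fracs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_peak_lands_in_max_bin(self):
        freqs = np.arange(0.0, 35.0001, 0.25)
        psd = 1.0 + 10.0 * np.exp(-0.5 * ((freqs - 10.0) / 0.5) ** 2)
        centers, fracs = relative_power_spectrum(
            PowerSpectrum(freqs=freqs, psd=psd))
        c = centers[np.argmax(fracs)]
        assert c - 0.25 <= 10.0 <= c + 0.25
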