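"""Apodization, coil combination, channel alignment, FFT and quality metrics."""

import numpy as np
import pytest

from downfield_mrs.fid import FidSeries
from downfield_mrs.processing import (
    align_and_reject_channels,
    apodize,
    combine_channels,
    measure_linewidth,
    measure_snr,
    to_spectrum,
)
from downfield_mrs.resonances import ResonanceSpec
from downfield_mrs.synthetic import AcquisitionProtocol, synthesize_fid

PROT = AcquisitionProtocol(noise_sigma=0.0, n_channels=1, n_points=4096)
H2_LIKE = [ResonanceSpec("H2", 9.3, "singlet", 0.0, 28.0, 1.0)]
TRP_LIKE = [ResonanceSpec("TRP", 10.1, "singlet", 0.0, 54.0, 1.0)]


def _tone(freq_hz: float, n=512, dwell=5e-4, channels=1) -> FidSeries:
    t = np.arange(n) * dwell
    s = np.exp(1j * 2 * np.pi * freq_hz * t)
    return FidSeries(np.tile(s, (channels, 1)), dwell, 297.2, 9.7)


class TestApodize:
    def test_zero_broadening_is_identity(self):
        fid = _tone(100.0)
        np.testing.assert_array_equal(apodize(fid, 0.0).samples, fid.samples)

    def test_last_sample_attenuation(self):
        fid = FidSeries(np.ones((1, 100)), 1e-3, 297.2, 9.7)
        out = apodize(fid, 5.0)
        t_last = 99 * 1e-3
        assert out.samples[0, -1] == pytest.approx(np.exp(-np.pi * 5 * t_last))

    def test_composition_is_additive(self):
        fid = _tone(150.0)
        a = apodize(apodize(fid, 2.0), 3.0)
        b = apodize(fid, 5.0)
        np.testing.assert_allclose(a.samples, b.samples, rtol=1e-12)

    def test_lorentzian_width_adds_line_broadening(self):
        fid = synthesize_fid(H2_LIKE, None, PROT)
        w0 = measure_linewidth(to_spectrum(fid), 9.3,
                               transmitter_freq=PROT.transmitter_freq)
        w5 = measure_linewidth(to_spectrum(apodize(fid, 5.0)), 9.3,
                               transmitter_freq=PROT.transmitter_freq)
        assert w0 == pytest.approx(28.0, abs=1.5)
        assert w5 == pytest.approx(33.0, abs=1.5)

    def test_rejects_negative_lb(self):
        with pytest.raises(ValueError):
            apodize(_tone(0.0), -1.0)


class TestCombineChannels:
    def _water_ref(self, weights, n=512, dwell=5e-4, noise=0.0, seed=0):
        t = np.arange(n) * dwell
        s = 100.0 * np.exp(-np.pi * 22.0 * t)
        samples = np.asarray(weights)[:, None] * s[None, :]
        if noise:
            rng = np.random.default_rng(seed)
            samples = samples + rng.normal(0, noise, (2, *samples.shape)).view()[0] \
                + 1j * rng.normal(0, noise, samples.shape)
        return FidSeries(samples, dwell, 297.2, 4.7)

    def test_single_channel_unit_magnitude_scaling(self):
        fid = _tone(100.0)
        ref = self._water_ref([1.0 + 0j])
        out = combine_channels(fid, ref)
        assert out.n_channels == 1
        np.testing.assert_allclose(np.abs(out.samples), np.abs(fid.samples),
                                   rtol=1e-12)

    def test_matched_filter_beats_single_channel(self):
        """Complex weights (1, i): combined SNR exceeds either channel's."""
        rng = np.random.default_rng(7)
        weights = np.array([1.0, 1j])
        t = np.arange(512) * 5e-4
        signal = np.exp((1j * 2 * np.pi * 119 - np.pi * 28) * t)
        noise = rng.normal(0, 0.05, (2, 2, 512))
        samples = weights[:, None] * signal[None, :] + noise[0] + 1j * noise[1]
        fid = FidSeries(samples, 5e-4, 297.2, 9.7)
        ref = self._water_ref(weights)
        combined = combine_channels(fid, ref)

        def snr_of(sample_row):
            spec = to_spectrum(FidSeries(sample_row[None, :], 5e-4, 297.2, 9.7))
            return measure_snr(spec, peak_ppm=9.7 + 119 / 297.2)

        snr_comb = snr_of(combined.samples[0])
        assert snr_comb > snr_of(fid.samples[0])
        assert snr_comb > snr_of(fid.samples[1])

    def test_fourchannel_snr_gain_near_two(self):
        """Equal-sensitivity 4-channel combination gains ~sqrt(4) in SNR."""
        rng = np.random.default_rng(11)
        t = np.arange(512) * 5e-4
        signal = np.exp((1j * 2 * np.pi * 119 - np.pi * 28) * t)
        gains = []
        for _ in range(30):
            noise = rng.normal(0, 0.08, (2, 4, 512))
            samples = np.tile(signal, (4, 1)) + noise[0] + 1j * noise[1]
            fid = FidSeries(samples, 5e-4, 297.2, 9.7)
            ref = self._water_ref(np.ones(4))
            combined = combine_channels(fid, ref)
            spec_c = to_spectrum(combined)
            spec_1 = to_spectrum(FidSeries(samples[:1], 5e-4, 297.2, 9.7))
            ppm = 9.7 + 119 / 297.2
            gains.append(measure_snr(spec_c, ppm) / measure_snr(spec_1, ppm))
        assert np.mean(gains) == pytest.approx(2.0, rel=0.2)

    def test_common_complex_scale_invariance(self):
        scale = 0.5 * np.exp(1j * 0.7)
        weights = np.array([1.0, 0.6 * np.exp(1j * 2.0)])
        t = np.arange(256) * 5e-4
        signal = np.exp((1j * 2 * np.pi * 119 - np.pi * 28) * t)
        samples = weights[:, None] * signal[None, :]
        fid = FidSeries(samples, 5e-4, 297.2, 9.7)
        ref = self._water_ref(weights, n=256)
        scaled_fid = fid.with_samples(samples * scale)
        scaled_ref = ref.with_samples(ref.samples * scale)
        a = combine_channels(fid, ref)
        b = combine_channels(scaled_fid, scaled_ref)
        np.testing.assert_allclose(np.abs(a.samples), np.abs(b.samples) /
                                   abs(scale), rtol=1e-10)

    def test_zero_water_reference_rejected(self):
        fid = _tone(100.0)
        ref = FidSeries(np.zeros((1, 512)), 5e-4, 297.2, 4.7)
        with pytest.raises(ValueError):
            combine_channels(fid, ref)


class TestAlignAndReject:
    def _multi(self, shift_hz=0.0, bad_channel=False, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(512) * 5e-4
        base = (np.exp((1j * 2 * np.pi * 119 - np.pi * 33) * t)
                + np.exp((1j * 2 * np.pi * (-59) - np.pi * 40) * t))
        rows = [base.copy() for _ in range(7)]
        rows.append(base * np.exp(1j * 2 * np.pi * shift_hz * t)
                    if not bad_channel else
                    rng.normal(0, 1.0, 512) + 1j * rng.normal(0, 1.0, 512))
        return FidSeries(np.stack(rows), 5e-4, 297.2, 9.7)

    def test_identical_channels_untouched(self):
        fid = self._multi()
        out, rejected = align_and_reject_channels(fid)
        assert rejected == []
        np.testing.assert_allclose(out.samples, fid.samples, rtol=1e-12)

    def test_recovers_imposed_frequency_shift(self):
        fid = self._multi(shift_hz=10.0)
        out, rejected = align_and_reject_channels(fid, max_shift=20.0)
        assert rejected == []
        df = 1.0 / (512 * 5e-4)
        applied = out.meta["channel_shifts_hz"][-1]
        assert applied == pytest.approx(-10.0, abs=df)

    def test_pure_noise_channel_rejected(self):
        fid = self._multi(bad_channel=True)
        out, rejected = align_and_reject_channels(fid)
        assert rejected == [7]
        assert out.n_channels == 7

    def test_all_rejected_raises(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(0, 1, (3, 512)) + 1j * rng.normal(0, 1, (3, 512))
        fid = FidSeries(samples, 5e-4, 297.2, 9.7)
        with pytest.raises(ValueError):
            align_and_reject_channels(fid, similarity_min=0.99)


class TestToSpectrum:
    def test_tone_lands_at_expected_ppm(self):
        spec = to_spectrum(_tone(200.0))
        peak_ppm = spec.ppm_axis[np.argmax(spec.magnitude)]
        assert peak_ppm == pytest.approx(9.7 + 200 / 297.2, abs=0.01)

    def test_parseval(self):
        fid = _tone(137.0)
        spec = to_spectrum(fid)
        e_time = np.sum(np.abs(fid.samples) ** 2)
        e_freq = np.sum(np.abs(spec.values) ** 2) / fid.n_points
        assert e_freq == pytest.approx(e_time, rel=1e-12)

    def test_trp_fixture_peaks_at_10_1(self):
        fid = synthesize_fid(TRP_LIKE, None, PROT)
        spec = to_spectrum(fid)
        assert spec.ppm_axis[np.argmax(spec.magnitude)] == pytest.approx(
            10.1, abs=0.02)

    def test_requires_single_channel(self):
        with pytest.raises(ValueError):
            to_spectrum(_tone(0.0, channels=2))


class TestMeasureSnr:
    def test_noiseless_is_infinite(self):
        spec = to_spectrum(synthesize_fid(H2_LIKE, None, PROT))
        assert measure_snr(spec) == np.inf

    def test_doubling_amplitude_doubles_snr(self):
        prot = AcquisitionProtocol(n_channels=1, noise_sigma=0.02)
        a = synthesize_fid(H2_LIKE, {"H2": 1.0}, prot, seed=5)
        b = synthesize_fid(H2_LIKE, {"H2": 2.0}, prot, seed=5)
        snr_a = measure_snr(to_spectrum(a))
        snr_b = measure_snr(to_spectrum(b))
        assert snr_b / snr_a == pytest.approx(2.0, rel=0.05)

    def test_calibrated_fixture_near_target(self, truth, fixed_channel_weights):
        """Default noise calibration lands within 20% of SNR 27."""
        from downfield_mrs.processing import process_scan
        from downfield_mrs.synthetic import generate_saturation_series

        snrs = []
        for seed in range(6):
            ds = generate_saturation_series(
                truth, AcquisitionProtocol(), seed=seed,
                channel_weights=fixed_channel_weights)
            snrs.append(measure_snr(to_spectrum(
                process_scan(ds.m0, ds.water_ref))))
        assert np.mean(snrs) == pytest.approx(27.0, rel=0.2)

    def test_empty_noise_window_raises(self):
        spec = to_spectrum(_tone(0.0))
        with pytest.raises(ValueError):
            measure_snr(spec, noise_window=(40.0, 41.0))


class TestMeasureLinewidth:
    def test_trp_default_width(self):
        spec = to_spectrum(synthesize_fid(TRP_LIKE, None, PROT))
        width = measure_linewidth(spec, 10.1,
                                  transmitter_freq=PROT.transmitter_freq)
        # the one-sided discrete transform broadens the apparent absorption
        # width by ~ linewidth * dwell relative to the continuous Lorentzian
        assert width == pytest.approx(54.0, abs=3.0)

    def test_interpolation_on_analytic_lorentzian(self):
        """FWHM from linear interpolation on an exactly sampled Lorentzian."""
        f_axis = np.linspace(400, -400, 2048)
        gamma = 17.0  # half width at half maximum
        mag = 1.0 / (1.0 + (f_axis / gamma) ** 2)
        from downfield_mrs.fid import Spectrum
        spec = Spectrum(mag.astype(complex), 9.7 + f_axis / 297.2)
        width = measure_linewidth(spec, 9.7, transmitter_freq=297.2)
        assert width == pytest.approx(2 * gamma, rel=5e-3)

    def test_missing_peak_raises(self):
        spec = to_spectrum(synthesize_fid(TRP_LIKE, None, PROT))
        with pytest.raises(ValueError):
            measure_linewidth(spec, 10.1)  # no transmitter frequency
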