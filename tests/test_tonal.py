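"""Decimation, spectrogram whitening/binarization and contour extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from hydroscape import synth
from hydroscape.calibration import CalibratedSegment
from hydroscape.tonal import (
    HF_FFT,
    LF_FFT,
    LF_RATE,
    decimate_lf,
    detect_tonals,
    extract_contours,
    spectrogram,
    whiten_binarize,
)
from tests.conftest import T0, make_segment


class TestDecimate:
    def test_passband_tone_preserved(self):
        fs = 32768
        t = np.arange(5 * fs) / fs
        seg = make_segment(1e5 * np.sin(2 * np.pi * 500.0 * t), fs)
        out = decimate_lf(seg)
        assert out.sample_rate == 3000
        rms_in = np.sqrt(np.mean(seg.pressure**2))
        rms_out = np.sqrt(np.mean(out.pressure[3000:-3000] ** 2))
        assert 20 * np.log10(rms_out / rms_in) == pytest.approx(0.0, abs=0.5)

    def test_stopband_tone_attenuated(self):
        fs = 32768
        t = np.arange(5 * fs) / fs
        seg = make_segment(1e5 * np.sin(2 * np.pi * 2500.0 * t), fs)
        out = decimate_lf(seg)
        rms_in = np.sqrt(np.mean(seg.pressure**2))
        rms_out = np.sqrt(np.mean(out.pressure[3000:-3000] ** 2))
        assert 20 * np.log10(rms_out / rms_in) < -20.0

    def test_zero_signal(self):
        seg = make_segment(np.zeros(32768), 32768)
        out = decimate_lf(seg)
        assert np.allclose(out.pressure, 0.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            decimate_lf(make_segment(np.zeros(2048), 2048))

    @pytest.mark.parametrize("fs", [8192, 16384, 32768])
    def test_all_standard_rates_reach_3000(self, fs):
        seg = make_segment(np.random.default_rng(0).standard_normal(fs * 2), fs)
        assert decimate_lf(seg).sample_rate == 3000


class TestSpectrogramGeometry:
    def test_lf_bin_width_is_5_86_hz(self):
        seg = make_segment(np.zeros(LF_RATE * 2), LF_RATE)
        spec = spectrogram(seg, LF_FFT)
        assert spec.bin_frequencies[1] == 3000 / 512
        assert spec.bin_frequencies[1] == pytest.approx(5.86, abs=0.004)

    def test_hf_bin_width_is_32_hz_at_32768(self):
        seg = make_segment(np.zeros(32768), 32768)
        spec = spectrogram(seg, HF_FFT)
        assert spec.bin_frequencies[1] == 32768 / 1024 == 32.0

    def test_hop_is_half_fft(self):
        seg = make_segment(np.zeros(LF_RATE * 2), LF_RATE)
        spec = spectrogram(seg, LF_FFT)
        assert spec.hop == LF_FFT // 2
        assert np.diff(spec.frame_times)[0] == pytest.approx(256 / 3000)


class TestWhitenBinarize:
    def _noise_spec(self, seed=0, seconds=60, fs=LF_RATE):
        rng = np.random.default_rng(seed)
        seg = make_segment(rng.standard_normal(seconds * fs), fs)
        return spectrogram(seg, LF_FFT)

    def test_stationary_noise_low_pixel_rate(self):
        rates = []
        for seed in range(20):
            binary = whiten_binarize(self._noise_spec(seed))
            rates.append(binary[50:].mean())
        assert np.mean(rates) < 0.02

    def test_injected_tone_column_true(self):
        # a call-length (2 s) tone well above background paints its bin
        # column; the decaying background tracker would eventually absorb
        # a much longer tone (time constant 1/α ≈ 50 frames ≈ 4 s)
        fs = LF_RATE
        rng = np.random.default_rng(1)
        t = np.arange(30 * fs) / fs
        noise = rng.standard_normal(len(t))
        tone = np.zeros_like(t)
        sl = slice(10 * fs, 12 * fs)
        tone[sl] = 8.0 * np.sin(2 * np.pi * 600.0 * t[sl])
        spec = spectrogram(make_segment(noise + tone, fs), LF_FFT)
        binary = whiten_binarize(spec)
        tone_bin = int(round(600.0 / (fs / LF_FFT)))
        frames = (spec.frame_times > 10.3) & (spec.frame_times < 11.7)
        assert binary[frames, tone_bin].mean() > 0.9

    def test_all_equal_spectrogram_all_false(self):
        seg = make_segment(np.zeros(LF_RATE * 5), LF_RATE)
        spec = spectrogram(seg, LF_FFT)
        assert not whiten_binarize(spec).any()

    def test_too_few_frames_rejected(self):
        seg = make_segment(np.zeros(LF_FFT * 2), LF_RATE)
        spec = spectrogram(seg, LF_FFT)
        with pytest.raises(ValueError):
            whiten_binarize(spec)


class TestContours:
    def test_downsweep_endpoints(self):
        spec = synth.SceneSpec(
            duration=20, sample_rate=8192, seed=2,
            events=[synth.EventSpec("downsweep", 8,
                                    {"f_start": 2000, "f_end": 500,
                                     "duration": 1.0, "snr": 20})])
        seg, truth, _ = synth.render_scene(spec)
        contours = detect_tonals(seg, "LF")
        assert len(contours) == 1
        c = contours[0]
        # the Hann amplitude envelope silences the sweep's extremes, so the
        # recovered span covers the portion above the noise (~600–1460 Hz
        # of the in-band 500–1500 Hz truth), monotonically decreasing
        assert c.max_freq < 1500
        assert c.min_freq < 650
        assert c.max_freq > 1300
        assert c.duration >= 0.5
        freqs = [f for _, f in c.contour]
        assert freqs[0] > freqs[-1]

    def test_two_simultaneous_tones(self):
        fs = 8192
        rng = np.random.default_rng(5)
        t = np.arange(20 * fs) / fs
        noise = rng.standard_normal(len(t))
        x = noise.copy()
        sl = slice(8 * fs, 12 * fs)
        for f in (600.0, 900.0):  # 300 Hz apart
            x[sl] += 0.8 * np.sin(2 * np.pi * f * t[sl])
        contours = detect_tonals(make_segment(x, fs), "LF")
        assert len(contours) == 2
        centres = sorted(np.mean([p[1] for p in c.contour]) for c in contours)
        assert centres[0] == pytest.approx(600, abs=12)
        assert centres[1] == pytest.approx(900, abs=12)

    def test_pure_noise_rarely_yields_contours(self):
        fails = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            seg = make_segment(rng.standard_normal(60 * 8192), 8192)
            fails += len(detect_tonals(seg, "LF")) > 0
        assert fails <= 1


class TestDetectTonals:
    def test_bearded_seal_trill_detected_by_both_paths(self):
        spec = synth.SceneSpec(
            duration=30, sample_rate=32768, seed=6,
            events=[synth.EventSpec("downsweep", 10,
                                    {"f_start": 2400, "f_end": 300,
                                     "duration": 2.0, "snr": 20})])
        seg, _, _ = synth.render_scene(spec)
        lf = detect_tonals(seg, "LF")
        hf = detect_tonals(seg, "HF")
        assert len(lf) >= 1 and all(c.max_freq < 1500 for c in lf)
        assert len(hf) >= 1 and all(c.min_freq >= 1500 for c in hf)

    def test_low_moan_lf_only(self):
        spec = synth.SceneSpec(
            duration=30, sample_rate=8192, seed=7,
            events=[synth.EventSpec("moan", 10,
                                    {"freq": 50, "duration": 1.0, "snr": 15})])
        seg, _, _ = synth.render_scene(spec)
        lf = detect_tonals(seg, "LF")
        hf = detect_tonals(seg, "HF")
        assert len(lf) == 1
        assert lf[0].min_freq == pytest.approx(50, abs=12)
        assert hf == []

    def test_click_train_yields_no_tonals(self):
        events = [synth.EventSpec("click", 5.0 + 0.5 * k,
                                  {"duration": 5e-4, "snr": 25})
                  for k in range(20)]
        spec = synth.SceneSpec(duration=30, sample_rate=32768, seed=8,
                               events=events)
        seg, _, _ = synth.render_scene(spec)
        assert detect_tonals(seg, "LF") == []
        assert detect_tonals(seg, "HF") == []

    def test_gain_invariance(self):
        spec = synth.SceneSpec(
            duration=20, sample_rate=8192, seed=9,
            events=[synth.EventSpec("moan", 8,
                                    {"freq": 120, "duration": 1.0, "snr": 18})])
        seg, _, _ = synth.render_scene(spec)
        c1 = detect_tonals(seg, "LF")
        doubled = CalibratedSegment(seg.pressure * 2, seg.start_time,
                                    seg.sample_rate)
        c2 = detect_tonals(doubled, "LF")
        assert len(c1) == len(c2) == 1
        assert c1[0].duration == pytest.approx(c2[0].duration, abs=0.1)
        assert c1[0].min_freq == pytest.approx(c2[0].min_freq, abs=1.0)

    def test_hf_requires_fast_rate(self):
        with pytest.raises(ValueError):
            detect_tonals(make_segment(np.zeros(3000 * 2), 3000), "HF")
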