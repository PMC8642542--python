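"""Third-octave band construction, TOL measurement, decade aggregation
and exceedance statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from hydroscape.bands import (
    DECADE_BANDS,
    DecadeBand,
    ThirdOctaveBand,
    band_filter_sos,
    bandwidth_compensation_db,
    decade_series,
    exceedance,
    nominal_bands,
    overlap_fraction,
    summarize_period,
    tol_series,
)
from tests.conftest import T0, make_segment

VLF, LF, MF = DECADE_BANDS


class TestBandGeometry:
    def test_paper_band_set_10_to_12500(self):
        bands = nominal_bands(10, 12500)
        assert len(bands) == 32
        assert bands[0].index == -20
        assert bands[-1].index == 11
        assert bands[0].exact_centre == pytest.approx(9.8431, abs=1e-4)
        assert bands[0].nominal_centre == 10.0

    def test_single_band_edges(self):
        (band,) = nominal_bands(1000, 1000)
        assert band.lower_edge == pytest.approx(890.90, abs=0.01)
        assert band.upper_edge == pytest.approx(1122.46, abs=0.01)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            nominal_bands(10, 5)

    def test_bands_tile_contiguously(self):
        bands = nominal_bands(10, 12500)
        for a, b in zip(bands, bands[1:]):
            assert a.upper_edge == pytest.approx(b.lower_edge, rel=1e-9)
            assert a.upper_edge / a.lower_edge == pytest.approx(2 ** (1 / 3), rel=1e-9)

    def test_overlap_fractions(self):
        band_250 = ThirdOctaveBand(-6)
        assert band_250.nominal_centre == 250.0
        assert overlap_fraction(band_250, LF) == 1.0
        band_100 = ThirdOctaveBand(-10)  # exact centre 99.21 Hz, straddles 100 Hz
        assert overlap_fraction(band_100, VLF) == pytest.approx(0.5054, abs=1e-4)
        band_31 = ThirdOctaveBand(-15)
        assert overlap_fraction(band_31, MF) == 0.0

    def test_bandwidth_compensation_matches_published_values(self):
        # comparison offsets for the 63/125 Hz MSFD bands and the 2 kHz band
        assert bandwidth_compensation_db(VLF, ThirdOctaveBand(-12)) == 8
        assert bandwidth_compensation_db(LF, ThirdOctaveBand(-9)) == 15
        assert bandwidth_compensation_db(MF, ThirdOctaveBand(3)) == 13

    def test_compensation_requires_overlap(self):
        with pytest.raises(ValueError):
            bandwidth_compensation_db(MF, ThirdOctaveBand(-15))

    def test_decade_band_validation(self):
        with pytest.raises(ValueError):
            DecadeBand(10.0, 50.0, "bad")


class TestTOLSeries:
    def test_tone_at_band_centre(self, tone_segment):
        (band,) = nominal_bands(250, 250)
        tols = tol_series(tone_segment, [band])
        # 1 Pa RMS = 120 dB re 1 µPa; near-unity passband gain at centre
        assert tols.levels[0, 0] == pytest.approx(120.0, abs=0.3)

    def test_white_noise_adjacent_band_step(self):
        rng = np.random.default_rng(42)
        fs = 8192
        seg = make_segment(1e4 * rng.standard_normal(1000 * fs), fs)
        bands = nominal_bands(200, 1600)
        tols = tol_series(seg, bands)
        means = tols.levels.mean(axis=0)
        steps = np.diff(means)
        # contiguous base-2 bands have a bandwidth ratio of 2^(1/3)
        assert np.allclose(steps, 10 * np.log10(2 ** (1 / 3)), atol=0.15)

    def test_zero_segment_gives_missing(self):
        seg = make_segment(np.zeros(12 * 8192))
        tols = tol_series(seg, nominal_bands(250, 250))
        assert np.isnan(tols.levels).all()

    def test_near_nyquist_band_omitted(self):
        seg = make_segment(np.ones(11 * 8192))
        with pytest.warns(UserWarning, match="Nyquist"):
            tols = tol_series(seg, nominal_bands(10, 12500))
        assert all(b.upper_edge <= 0.95 * 4096 for b in tols.bands)

    def test_trailing_partial_window_discarded_and_first_flagged(self, tone_segment):
        tols = tol_series(tone_segment, nominal_bands(250, 250), window=3.0)
        assert len(tols.window_start_times) == 3  # 10 s → three 3-s windows
        assert tols.startup_flag[0] and not tols.startup_flag[1:].any()

    def test_filter_bank_energy_conservation(self):
        rng = np.random.default_rng(7)
        fs = 8192
        x = 1e4 * rng.standard_normal(60 * fs)
        seg = make_segment(x, fs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tols = tol_series(seg, nominal_bands(10, 12500))
        total_banded = 10 * np.log10(np.sum(10 ** (tols.levels / 10), axis=1))
        # broadband oracle restricted to the same frequency span
        sos = signal.butter(3, [tols.bands[0].lower_edge,
                                tols.bands[-1].upper_edge],
                            btype="bandpass", fs=fs, output="sos")
        y = signal.sosfilt(sos, x)[: len(total_banded) * 10 * fs]
        broadband = 20 * np.log10(np.sqrt(np.mean(
            y.reshape(-1, 10 * fs) ** 2, axis=1)))
        assert np.allclose(total_banded[1:], broadband[1:], atol=1.0)

    def test_band_selectivity_six_pole(self):
        # a centre-band tone must read ≥ 15 dB lower in the adjacent bands,
        # checked directly on the filter frequency response
        for n in (-10, 0, 5):
            band = ThirdOctaveBand(n)
            fs = 32768
            for neighbour in (ThirdOctaveBand(n - 1), ThirdOctaveBand(n + 1)):
                sos = band_filter_sos(neighbour, fs)
                w, h = signal.sosfreqz(sos, worN=[band.exact_centre], fs=fs)
                assert 20 * np.log10(np.abs(h[0])) < -15.0


class TestDecadeSeries:
    def test_flat_noise_decade_vs_125_band(self):
        rng = np.random.default_rng(3)
        fs = 8192
        seg = make_segment(1e4 * rng.standard_normal(300 * fs), fs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tols = tol_series(seg, nominal_bands(10, 1250))
        dec = decade_series(tols)
        idx125 = [b.nominal_centre for b in tols.bands].index(125.0)
        diff = dec["LF"].mean() - tols.levels[:, idx125].mean()
        assert diff == pytest.approx(10 * np.log10(900 / 28.94), abs=0.5)

    def test_single_tone_dominates_decade(self, tone_segment):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tols = tol_series(tone_segment, nominal_bands(10, 1250))
        dec = decade_series(tols)
        idx250 = [b.nominal_centre for b in tols.bands].index(250.0)
        # 0.15 dB headroom: the tone leaks ~−18 dB into each neighbouring
        # band through the 6-pole filter skirts, adding ~0.13 dB to the sum
        assert dec["LF"].iloc[0] == pytest.approx(tols.levels[0, idx250], abs=0.15)

    def test_identical_levels_closed_form(self):
        bands = tuple(nominal_bands(125, 800))
        from hydroscape.bands import TOLSeries, overlap_fraction
        L = 100.0
        tols = TOLSeries(
            pd.DatetimeIndex([T0]), bands, np.full((1, len(bands)), L))
        dec = decade_series(tols, (LF,))
        W = sum(overlap_fraction(b, LF) for b in bands)
        assert dec["LF"].iloc[0] == pytest.approx(L + 10 * np.log10(W), abs=1e-9)

    def test_no_overlap_gives_missing(self, tone_segment):
        tols = tol_series(tone_segment, nominal_bands(250, 250))
        dec = decade_series(tols, (MF,))
        assert dec["MF"].isna().all()

    def test_decade_vs_direct_decade_filter(self):
        # the fractional-overlap summation must agree with one direct
        # Butterworth decade-band measurement on a flat spectrum
        rng = np.random.default_rng(11)
        fs = 8192
        x = 1e4 * rng.standard_normal(120 * fs)
        seg = make_segment(x, fs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tols = tol_series(seg, nominal_bands(10, 1250))
        dec = decade_series(tols, (LF,))
        sos = signal.butter(3, [100, 1000], btype="bandpass", fs=fs, output="sos")
        y = signal.sosfilt(sos, x)
        direct = 20 * np.log10(np.sqrt(np.mean(y[fs * 10:] ** 2)))
        assert dec["LF"].iloc[1:].mean() == pytest.approx(direct, abs=0.5)


class TestExceedance:
    def test_constant_vector(self):
        tab = exceedance(np.full(50, 97.0))
        assert (tab == 97.0).all()

    def test_linear_interpolation_on_1_to_100(self):
        tab = exceedance(np.arange(1.0, 101.0), (10,))
        assert tab[10] == pytest.approx(90.1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            exceedance(np.array([np.nan]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=200,
                              allow_nan=False), min_size=1, max_size=300))
    def test_monotone_nonincreasing_in_p(self, levels):
        tab = exceedance(np.array(levels))
        assert (np.diff(tab.to_numpy()) <= 1e-12).all()


class TestPeriodSummaries:
    def _tols(self, start, hours, level):
        bands = tuple(nominal_bands(125, 125))
        times = pd.date_range(start, periods=hours * 360, freq="10s")
        from hydroscape.bands import TOLSeries
        return TOLSeries(times, bands,
                         np.full((len(times), 1), float(level)))

    def test_weekly_median_of_constant(self):
        tols = self._tols("2019-01-07", 7 * 24, 100.0)  # one ISO week
        out = summarize_period(tols, "weekly")
        assert len(out) == 1
        assert out.iloc[0, 0] == 100.0

    def test_monthly_boundary_counts(self):
        from hydroscape.bands import TOLSeries
        bands = tuple(nominal_bands(125, 125))
        times = pd.date_range("2019-06-30 23:00", periods=12 * 360, freq="10s")
        tols = TOLSeries(times, bands, np.full((len(times), 1), 90.0))
        out = summarize_period(tols, "monthly")
        assert list(out.index) == [(2019, 6), (2019, 7)]

    def test_level_shift_between_months_recovered(self):
        a = self._tols("2019-06-01", 48, 90.0)
        b = self._tols("2019-09-01", 48, 110.0)
        from hydroscape.bands import TOLSeries
        tols = TOLSeries.concat([a, b])
        out = summarize_period(tols, "monthly")
        assert (out.loc[(2019, 9)].iloc[0]
                - out.loc[(2019, 6)].iloc[0]) == pytest.approx(20.0, abs=1.0)
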