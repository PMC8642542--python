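"""Third-octave and decade band levels with exceedance statistics.

Third-octave bands use base-2 ANSI centre frequencies: exact centre
``1000 · 2^(n/3)`` Hz for integer index *n*, band edges ``centre · 2^(∓1/6)``,
so contiguous bands tile the axis (upper edge of band *n* equals the lower
edge of band *n+1*). Levels are RMS sound pressure in dB re 1 µPa measured
after a 6-pole Butterworth band-pass filter in concurrent non-overlapping
10-s windows. Decade levels (10–100, 100–1000, 1000–10000 Hz) are formed by
summing the third-octave intensities, scaling partially overlapping bands
by their linear-frequency overlap fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

TOL_WINDOW_S = 10.0
EXCEEDANCE_PERCENTAGES = (1, 5, 10, 25, 50, 75, 90, 95, 99)

_NOMINAL_MANTISSAS = np.array([1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0])


@dataclass(frozen=True)
class ThirdOctaveBand:
    """One base-2 third-octave band, identified by its integer index n."""

    index: int

    @property
    def exact_centre(self) -> float:
        return 1000.0 * 2.0 ** (self.index / 3.0)

    @property
    def nominal_centre(self) -> float:
        """Standard nominal centre (preferred-number rounding of the exact centre)."""
        c = self.exact_centre
        decade = np.floor(np.log10(c))
        candidates = np.concatenate(
            [_NOMINAL_MANTISSAS * 10.0 ** (decade + k) for k in (-1, 0, 1)])
        return float(candidates[np.argmin(np.abs(np.log10(candidates / c)))])

    @property
    def lower_edge(self) -> float:
        return self.exact_centre * 2.0 ** (-1.0 / 6.0)

    @property
    def upper_edge(self) -> float:
        return self.exact_centre * 2.0 ** (1.0 / 6.0)

    @property
    def bandwidth(self) -> float:
        return self.upper_edge - self.lower_edge

    def __repr__(self) -> str:  # pragma: no cover
        return f"ThirdOctaveBand(n={self.index}, nominal={self.nominal_centre:g} Hz)"


@dataclass(frozen=True)
class DecadeBand:
    """A band spanning one factor of ten in frequency."""

    lower: float
    upper: float
    label: str

    def __post_init__(self) -> None:
        if not np.isclose(self.upper, 10.0 * self.lower):
            raise ValueError("decade band must satisfy upper = 10 × lower")

    @property
    def bandwidth(self) -> float:
        return self.upper - self.lower


DECADE_BANDS = (
    DecadeBand(10.0, 100.0, "VLF"),
    DecadeBand(100.0, 1000.0, "LF"),
    DecadeBand(1000.0, 10000.0, "MF"),
)


@dataclass
class TOLSeries:
    """Matrix of windowed third-octave levels (dB re 1 µPa RMS).

    ``levels`` has shape (windows, bands); missing windows are NaN.
    ``startup_flag`` marks the first window of each contiguous segment,
    which contains the band filters' start-up transient (flagged, not
    dropped).
    """

    window_start_times: pd.DatetimeIndex
    bands: tuple[ThirdOctaveBand, ...]
    levels: np.ndarray
    window_length: float = TOL_WINDOW_S
    startup_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.window_start_times), len(self.bands)):
            raise ValueError("levels shape must be (windows, bands)")
        if self.startup_flag is None:
            self.startup_flag = np.zeros(len(self.window_start_times), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame indexed by window start, columns = nominal centres."""
        return pd.DataFrame(
            self.levels,
            index=self.window_start_times,
            columns=[b.nominal_centre for b in self.bands],
        )

    def to_long(self) -> pd.DataFrame:
        """Long (time, band_centre_nominal, level_db) DataFrame."""
        df = self.to_frame().reset_index(names="time")
        return df.melt(id_vars="time", var_name="band_centre_nominal",
                       value_name="level_db")

    @classmethod
    def concat(cls, parts: list["TOLSeries"]) -> "TOLSeries":
        if not parts:
            raise ValueError("nothing to concatenate")
        bands = parts[0].bands
        if any(p.bands != bands for p in parts):
            raise ValueError("band sets differ between parts")
        return cls(
            window_start_times=pd.DatetimeIndex(
                np.concatenate([p.window_start_times.values for p in parts])),
            bands=bands,
            levels=np.concatenate([p.levels for p in parts], axis=0),
            window_length=parts[0].window_length,
            startup_flag=np.concatenate([p.startup_flag for p in parts]),
        )


def nominal_bands(f_min_nominal: float, f_max: float) -> list[ThirdOctaveBand]:
    """All third-octave bands with nominal centre in [f_min_nominal, f_max].

    E.g. (10, 12500) yields the 32 bands n = −20…11 used at a 32768 Hz
    sampling rate.
    """
    if f_max < f_min_nominal:
        raise ValueError(
            f"f_max ({f_max} Hz) must be ≥ f_min_nominal ({f_min_nominal} Hz)")
    if f_min_nominal < 1.0:
        raise ValueError("f_min_nominal must be ≥ 1 Hz")
    n_lo = int(np.floor(3 * np.log2(f_min_nominal / 1000.0))) - 2
    n_hi = int(np.ceil(3 * np.log2(f_max / 1000.0))) + 2
    out = []
    for n in range(n_lo, n_hi + 1):
        band = ThirdOctaveBand(n)
        if f_min_nominal <= band.nominal_centre <= f_max:
            out.append(band)
    return out


def band_filter_sos(band: ThirdOctaveBand, sample_rate: float) -> np.ndarray:
    """6-pole Butterworth band-pass for one third-octave band.

    Band-pass with 6 poles total (3rd-order low-pass prototype), returned
    as second-order sections for numerical stability at low centre
    frequencies relative to the sampling rate.
    """
    return signal.butter(
        3, [band.lower_edge, band.upper_edge], btype="bandpass",
        fs=sample_rate, output="sos")


def tol_series(
    segment,
    bands: list[ThirdOctaveBand],
    window: float = TOL_WINDOW_S,
) -> TOLSeries:
    """Windowed third-octave levels of one contiguous calibrated segment.

    Each band filter runs once over the whole segment (stateful, causal);
    the filtered output is then sliced into non-overlapping ``window``-s
    windows and the RMS level computed per window. The trailing partial
    window is discarded; the first window carries the filter start-up
    transient and is flagged. Bands whose upper edge exceeds 0.95× the
    Nyquist frequency are omitted with a warning. Silent windows yield NaN.
    """
    fs = segment.sample_rate
    nyq = fs / 2.0
    kept = []
    for band in bands:
        if band.upper_edge > 0.95 * nyq:
            warnings.warn(
                f"band n={band.index} (nominal {band.nominal_centre:g} Hz) "
                f"exceeds 0.95×Nyquist at fs={fs} Hz; omitted", stacklevel=2)
        else:
            kept.append(band)
    wlen = int(round(window * fs))
    if len(segment.pressure) < wlen:
        raise ValueError("segment shorter than one analysis window")
    n_win = len(segment.pressure) // wlen
    x = np.asarray(segment.pressure, dtype=np.float64)[: n_win * wlen]
    levels = np.full((n_win, len(kept)), np.nan)
    for j, band in enumerate(kept):
        sos = band_filter_sos(band, fs)
        y = signal.sosfilt(sos, x)
        rms = np.sqrt(np.mean(y.reshape(n_win, wlen) ** 2, axis=1))
        with np.errstate(divide="ignore"):
            lev = 20.0 * np.log10(rms)
        levels[:, j] = np.where(rms > 0, lev, np.nan)
    times = segment.start_time + pd.to_timedelta(np.arange(n_win) * window, unit="s")
    startup = np.zeros(n_win, dtype=bool)
    startup[0] = True
    return TOLSeries(pd.DatetimeIndex(times), tuple(kept), levels,
                     window_length=window, startup_flag=startup)


def overlap_fraction(band: ThirdOctaveBand, decade: DecadeBand) -> float:
    """Linear-frequency overlap of a third-octave band with a decade band,
    as a fraction of the third-octave bandwidth."""
    overlap = max(0.0, min(band.upper_edge, decade.upper)
                  - max(band.lower_edge, decade.lower))
    return overlap / band.bandwidth


def decade_series(
    tols: TOLSeries,
    decades: tuple[DecadeBand, ...] = DECADE_BANDS,
) -> pd.DataFrame:
    """Per-window decade levels by intensity summation of third-octave levels.

    L_dec = 10·log10( Σ_b w_b · 10^(L_b/10) ) with w_b the linear overlap
    fraction. A decade with no overlapping band present yields NaN.
    """
    out = {}
    intens = 10.0 ** (tols.levels / 10.0)
    for dec in decades:
        w = np.array([overlap_fraction(b, dec) for b in tols.bands])
        if not np.any(w > 0):
            out[dec.label] = np.full(len(tols.window_start_times), np.nan)
            continue
        weighted = intens * w
        total = np.nansum(np.where(w > 0, weighted, 0.0), axis=1)
        all_missing = np.all(np.isnan(tols.levels[:, w > 0]), axis=1)
        with np.errstate(divide="ignore"):
            lev = 10.0 * np.log10(total)
        out[dec.label] = np.where(all_missing | (total <= 0), np.nan, lev)
    return pd.DataFrame(out, index=tols.window_start_times)


def bandwidth_compensation_db(decade: DecadeBand, band: ThirdOctaveBand) -> int:
    """10·log10 of the decade/third-octave bandwidth ratio, rounded to dB.

    Used to compare absolute levels between a decade band and an indicator
    third-octave band inside it (e.g. the 63 and 125 Hz Marine Strategy
    Framework Directive bands and the 2 kHz band): 8, 15 and 13 dB for
    (10–100 Hz, 63 Hz), (100–1000 Hz, 125 Hz) and (1–10 kHz, 2 kHz).
    """
    if overlap_fraction(band, decade) <= 0:
        raise ValueError(
            f"band n={band.index} does not overlap decade {decade.label}")
    return int(round(10.0 * np.log10(decade.bandwidth / band.bandwidth)))


def exceedance(
    levels: np.ndarray,
    p_list: tuple[int, ...] = EXCEEDANCE_PERCENTAGES,
) -> pd.Series:
    """Exceedance levels L_p: the level exceeded by p% of measurements.

    L_p is the (100−p)-th percentile of the dB values with linear
    interpolation between order statistics; L_1 tracks the loud tail and
    L_99 the quiet floor, so L_p is non-increasing in p.
    """
    vals = np.asarray(levels, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("exceedance requires at least one finite level")
    lp = np.percentile(vals, [100.0 - p for p in p_list])
    return pd.Series(lp, index=pd.Index(list(p_list), name="p"), name="L_p")


def summarize_period(
    tols: TOLSeries,
    period: str = "weekly",
    statistic: str = "median",
) -> pd.DataFrame:
    """Weekly (ISO week) or monthly (calendar month) summaries of the TOLs.

    ``statistic='median'`` returns one row per period with the median dB
    level per band; ``statistic='exceedance'`` returns a row per
    (period, p) with the full exceedance set per band.
    """
    if period not in {"weekly", "monthly"}:
        raise ValueError("period must be 'weekly' or 'monthly'")
    df = tols.to_frame()
    if period == "weekly":
        iso = df.index.isocalendar()
        keys = [iso["year"].to_numpy(), iso["week"].to_numpy()]
        names = ["iso_year", "iso_week"]
    else:
        keys = [df.index.year, df.index.month]
        names = ["year", "month"]
    grouped = df.groupby([pd.Index(k, name=n) for k, n in zip(keys, names)])
    if statistic == "median":
        return grouped.median()
    if statistic == "exceedance":
        parts = {}
        for key, sub in grouped:
            tab = sub.apply(lambda col: exceedance(col.to_numpy())
                            if np.isfinite(col).any() else
                            pd.Series(np.nan, index=pd.Index(
                                list(EXCEEDANCE_PERCENTAGES), name="p")))
            parts[key] = tab
        out = pd.concat(parts, names=names)
        return out
    raise ValueError("statistic must be 'median' or 'exceedance'")
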