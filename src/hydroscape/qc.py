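"""Flow-noise and recorder self-noise diagnostics.

Flow pseudo-noise over a moored hydrophone is usually tidally modulated, so
a periodogram of the hourly median third-octave levels shows a marked
~6 or ~12-h peak in the affected (low-frequency) bands. Recorder self-noise
censors the ambient level distribution from below; a band is flagged as
self-noise limited if the quiet-end exceedance levels L_99 and L_90 differ
by less than 0.5 dB, or if the level distribution has substantial
probability mass piled at its minimum (the "lowermost violin width" rule).
These are QC annotations only — no level correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hydroscape.bands import ThirdOctaveBand, TOLSeries, exceedance

TIDAL_PERIOD_WINDOWS_H = ((5.5, 6.8), (11.5, 13.0))
TIDAL_PROMINENCE_DB = 6.0
SELF_NOISE_L99_L90_DB = 0.5
SELF_NOISE_VIOLIN_RATIO = 0.05
MIN_LEVELS_FOR_ASSESSMENT = 100


@dataclass
class BandDiagnostics:
    """QC result for one third-octave band."""

    band: ThirdOctaveBand
    flow_noise_flag: bool
    tidal_peak_period: float | None
    self_noise_flag: bool | None  # None = indeterminate (too few levels)
    self_noise_estimate: float | None
    rule_fired: str  # exceedance_rule | violin_rule | none | indeterminate

    def __post_init__(self) -> None:
        if bool(self.self_noise_flag) != (self.self_noise_estimate is not None):
            raise ValueError("estimate must be present iff flagged")


def hourly_median_tols(tols: TOLSeries) -> pd.DataFrame:
    """Median of the 10-s levels per clock hour and band.

    Indexed by hour start; hours without any window are absent (not NaN-
    filled), respecting duty cycles.
    """
    df = tols.to_frame()
    out = df.groupby(df.index.floor("h")).median()
    return out.dropna(how="all")


def tol_periodogram(hourly: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of an hourly level series, on a period axis.

    The series is placed on a regular hourly grid (gaps filled with the
    series median), the mean removed, and the absolute FFT taken with FFT
    size equal to the number of hourly estimates; bin k of an N-point
    series corresponds to a period of N/k hours. Returns (period_hours,
    magnitude) for k = 1 … N//2.
    """
    hourly = hourly.dropna()
    if len(hourly) < 48:
        raise ValueError("insufficient duration: need ≥ 48 hourly estimates")
    grid = pd.date_range(hourly.index.min(), hourly.index.max(), freq="h")
    filled = hourly.reindex(grid)
    filled = filled.fillna(filled.median())
    x = filled.to_numpy(dtype=float)
    x = x - x.mean()
    n = len(x)
    mag = np.abs(np.fft.rfft(x))[1: n // 2 + 1]
    k = np.arange(1, len(mag) + 1)
    periods = n / k
    return periods, mag


def tidal_flag(
    periods: np.ndarray,
    magnitude: np.ndarray,
    prominence_db: float = TIDAL_PROMINENCE_DB,
) -> tuple[bool, float | None]:
    """Flag a tidal (~6/12-h) signature in a level periodogram.

    True if a local maximum with period in [5.5, 6.8] h or [11.5, 13.0] h
    exceeds the loudest magnitude *outside* those period windows by at
    least ``prominence_db`` (on 20·log10 magnitude). Measuring prominence
    against the off-window maximum rather than the median makes the flag
    robust to the heavy-tailed spread of raw single-bin FFT magnitudes
    (the extreme of ~30 Rayleigh bins routinely sits > 6 dB above the
    median even for white input, whereas a genuine tidal line dominates
    the entire spectrum). Returns (flag, peak period or None).
    """
    mag_db = 20.0 * np.log10(np.maximum(magnitude, 1e-300))
    in_window = np.array([
        any(lo <= p <= hi for lo, hi in TIDAL_PERIOD_WINDOWS_H) for p in periods])
    if not in_window.any() or in_window.all():
        return False, None
    off_max = mag_db[~in_window].max()
    best: tuple[float, float] | None = None  # (mag_db, period)
    for i in np.nonzero(in_window)[0]:
        left = mag_db[i - 1] if i > 0 else -np.inf
        right = mag_db[i + 1] if i + 1 < len(mag_db) else -np.inf
        if (mag_db[i] >= left and mag_db[i] >= right
                and mag_db[i] - off_max >= prominence_db):
            if best is None or mag_db[i] > best[0]:
                best = (mag_db[i], periods[i])
    if best is None:
        return False, None
    return True, float(best[1])


def self_noise_assess(
    band_levels: np.ndarray,
    l99_l90_db: float = SELF_NOISE_L99_L90_DB,
    violin_ratio: float = SELF_NOISE_VIOLIN_RATIO,
) -> tuple[bool | None, float | None, str]:
    """Assess one band's level distribution for self-noise limitation.

    Rule 1 (takes precedence): |L_90 − L_99| < 0.5 dB → flagged, estimate
    L_99. Rule 2: Gaussian kernel density (Silverman bandwidth) evaluated
    at the minimum observed level exceeds 0.05 of the maximum density →
    flagged, estimate = minimum level. Fewer than 100 values →
    indeterminate (None, None, 'indeterminate').
    """
    vals = np.asarray(band_levels, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_LEVELS_FOR_ASSESSMENT:
        return None, None, "indeterminate"
    exc = exceedance(vals, (90, 99))
    if abs(exc[90] - exc[99]) < l99_l90_db:
        return True, float(exc[99]), "exceedance_rule"
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 512)
    density = kde(grid)
    if kde(vals.min())[0] / density.max() > violin_ratio:
        return True, float(vals.min()), "violin_rule"
    return False, None, "none"


def self_noise_curve(
    centre_frequencies: np.ndarray,
    estimates_db: np.ndarray,
) -> np.ndarray:
    """Least-squares cubic of self-noise estimate vs log10(frequency).

    Returns polynomial coefficients (highest degree first, numpy
    convention) of estimate (dB) as a cubic in log10(centre Hz). Requires
    at least 4 flagged bands.
    """
    f = np.asarray(centre_frequencies, dtype=float)
    y = np.asarray(estimates_db, dtype=float)
    if f.size < 4:
        raise ValueError("cubic self-noise fit requires ≥ 4 flagged bands")
    return np.polyfit(np.log10(f), y, 3)


def band_diagnostics(tols: TOLSeries) -> list[BandDiagnostics]:
    """Run the flow-noise and self-noise diagnostics for every band."""
    hourly = hourly_median_tols(tols)
    out = []
    for j, band in enumerate(tols.bands):
        series = hourly.iloc[:, j].dropna()
        try:
            flag, period = tidal_flag(*tol_periodogram(series))
        except ValueError:
            flag, period = False, None
        sn_flag, sn_est, rule = self_noise_assess(tols.levels[:, j])
        out.append(BandDiagnostics(band, flag, period, sn_flag, sn_est, rule))
    return out


def diagnostics_frame(diags: list[BandDiagnostics]) -> pd.DataFrame:
    """Per-band diagnostics as a DataFrame ready for CSV export."""
    return pd.DataFrame(
        {
            "band_centre_nominal": [d.band.nominal_centre for d in diags],
            "flow_noise_flag": [d.flow_noise_flag for d in diags],
            "tidal_peak_period_h": [d.tidal_peak_period for d in diags],
            "self_noise_flag": [d.self_noise_flag for d in diags],
            "self_noise_estimate_db": [d.self_noise_estimate for d in diags],
            "rule_fired": [d.rule_fired for d in diags],
        }
    )
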