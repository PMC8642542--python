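"""Reporting products: calendar-resolution series and level distributions.

Detector outputs and band levels are summarised into 10-min (or daily)
calendar bins suitable for circular one-year presentation, weekly/monthly
level tables, and violin/box summaries of decade-level distributions.
Bins tile the analysis period half-open; bins falling entirely inside
duty-cycle gaps are absent (NaN), never zero, so scheduled silence is
distinguishable from measured quiet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hydroscape.bands import EXCEEDANCE_PERCENTAGES, exceedance


def bin_counts(
    event_times,
    bin: str | pd.Timedelta = "10min",
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
    recording_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
) -> pd.Series:
    """Event counts per half-open calendar bin.

    An event exactly on a bin boundary counts in the later bin. Bins with
    no recorded audio (per ``recording_intervals``) are NaN rather than 0.
    """
    times = pd.DatetimeIndex([t.time if hasattr(t, "time") and not callable(t.time)
                              else t for t in event_times])
    freq = pd.tseries.frequencies.to_offset(bin)
    if start is None:
        if len(times) == 0:
            raise ValueError("empty event list requires explicit start/end")
        start = times.min()
    if end is None:
        end = times.max() + freq
    grid = pd.date_range(pd.Timestamp(start).floor(freq), end, freq=freq,
                         inclusive="left")
    counts = pd.Series(0, index=grid, dtype=float)
    if len(times):
        binned = times.floor(freq)
        vc = pd.Series(binned).value_counts()
        counts.loc[vc.index.intersection(grid)] = vc.reindex(
            vc.index.intersection(grid)).to_numpy(dtype=float)
    if recording_intervals is not None:
        step = pd.to_timedelta(freq)
        recorded = np.zeros(len(grid), dtype=bool)
        for r0, r1 in recording_intervals:
            recorded |= (grid < r1) & (grid + step > r0)
        counts[~recorded] = np.nan
    counts.index.name = "bin_start"
    return counts


def decade_distribution(values: np.ndarray, grid_points: int = 256) -> dict:
    """Violin/box summary of a decade-level distribution.

    Returns a dict with a kernel-density curve (``grid``, ``density``),
    quartiles and the standard exceedance set (L_1 … L_99). A constant
    input degenerates to a spike (density None, all levels equal).
    Requires ≥ 100 values.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ValueError("decade distribution summary requires ≥ 100 values")
    exc = exceedance(vals, EXCEEDANCE_PERCENTAGES)
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    if np.ptp(vals) == 0:
        return {"grid": None, "density": None, "quartiles": (q1, q2, q3),
                "exceedance": exc, "n": int(vals.size)}
    kde = stats.gaussian_kde(vals)
    pad = 0.1 * np.ptp(vals)
    grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_points)
    return {"grid": grid, "density": kde(grid), "quartiles": (q1, q2, q3),
            "exceedance": exc, "n": int(vals.size)}


def yearly_truncate(product: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Keep only the first 365 days from the first retained sample.

    Calendar (circular) products represent one year; longer series are
    truncated for plotting.
    """
    if len(product) == 0:
        return product
    cutoff = product.index.min() + pd.Timedelta(days=365)
    return product.loc[product.index < cutoff]


def daily_median(frame: pd.DataFrame) -> pd.DataFrame:
    """Daily median of a time-indexed level table (e.g. TOLs per band)."""
    return frame.groupby(frame.index.floor("D")).median()


def weekly_median(frame: pd.DataFrame) -> pd.DataFrame:
    """ISO-week median of a time-indexed level table.

    Weeks pool same-week data across years per station (matching circular
    one-year presentation); use :func:`weekly_median_by_year` to keep
    years apart.
    """
    iso = frame.index.isocalendar()
    return frame.groupby(pd.Index(iso["week"].to_numpy(), name="iso_week")).median()


def weekly_median_by_year(frame: pd.DataFrame) -> pd.DataFrame:
    iso = frame.index.isocalendar()
    return frame.groupby([
        pd.Index(iso["year"].to_numpy(), name="iso_year"),
        pd.Index(iso["week"].to_numpy(), name="iso_week"),
    ]).median()


def plot_calendar(counts: pd.Series, path, title: str = "") -> None:
    """Render a calendar product on a circular (one-year) axis.

    A thin optional layer over the numeric products: the angle is the
    fraction of the year elapsed, the radius the binned value. Absent
    (duty-cycle) bins leave gaps. Correctness lives in the numbers; this
    is presentation only.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = yearly_truncate(counts.dropna())
    if len(counts) == 0:
        raise ValueError("nothing to plot")
    t0 = counts.index.min()
    angle = ((counts.index - t0).total_seconds()
             / pd.Timedelta(days=365).total_seconds() * 2 * np.pi)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.plot(angle, counts.to_numpy(), lw=0.8)
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def monthly_exceedance(frame: pd.DataFrame) -> pd.DataFrame:
    """Per calendar month, the exceedance set per column (band)."""
    parts = {}
    for (year, month), sub in frame.groupby([frame.index.year, frame.index.month]):
        cols = {}
        for col in sub.columns:
            vals = sub[col].to_numpy()
            if np.isfinite(vals).any():
                cols[col] = exceedance(vals)
            else:
                cols[col] = pd.Series(
                    np.nan, index=pd.Index(list(EXCEEDANCE_PERCENTAGES), name="p"))
        parts[(year, month)] = pd.DataFrame(cols)
    return pd.concat(parts, names=["year", "month"])
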