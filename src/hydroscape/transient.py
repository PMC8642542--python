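"""Transient (impulsive) sound detectors.

Two complementary detectors: a click detector for short broadband
transients, based on the dB difference between a fast and a slow
exponential moving average of the squared, high-passed (4-pole
Butterworth, 3000 Hz) signal; and an energy-sum detector for longer
low-frequency impulses such as seismic airgun pulses, based on the summed
spectrogram energy between 0 and 600 Hz relative to a slowly adapting
background. The averaging-length difference between the click detector's
signal and noise windows is four orders of magnitude while the level is
below threshold and five while above, so the noise estimate effectively
freezes during an event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from hydroscape.calibration import CalibratedSegment
from hydroscape.tonal import SpectrogramBlock

CLICK_THRESHOLD_DB = 12.0
CLICK_HIGHPASS_HZ = 3000.0
CLICK_FAST_ALPHA = 0.1
CLICK_SLOW_ALPHA_BELOW = 1e-5
CLICK_SLOW_ALPHA_ABOVE = 1e-6
CLICK_MERGE_GAP_S = 2e-3
CLICK_MIN_DURATION_S = 1e-4
CLICK_MAX_DURATION_S = 50e-3

ENERGY_SUM_THRESHOLD_DB = 8.0
ENERGY_SUM_ALPHA = 0.005
ENERGY_SUM_BAND = (0.0, 600.0)
ENERGY_SUM_MIN_FRAMES = 1  # short in-band pulses can occupy a single frame


@dataclass
class TransientDetection:
    """One timestamped impulsive event."""

    time: pd.Timestamp
    duration: float
    peak_snr: float
    detector: str               # click | energy_sum
    band: tuple[float, float]

    @property
    def offset_s(self) -> float:
        """Seconds from the Unix epoch (convenient for interval arithmetic)."""
        return self.time.value / 1e9


def _dual_ema_events_py(e, thr_lin, a_fast, a_slow_below, a_slow_above, slow0):
    fast = slow0
    slow = max(slow0, 1e-300)
    starts, ends, peaks = [], [], []
    open_i = -1
    peak = 0.0
    for i in range(len(e)):
        fast += a_fast * (e[i] - fast)
        above = fast > thr_lin * slow
        if above:
            if open_i < 0:
                open_i = i
                peak = fast / slow
            else:
                peak = max(peak, fast / slow)
            slow += a_slow_above * (e[i] - slow)
        else:
            if open_i >= 0:
                starts.append(open_i)
                ends.append(i)
                peaks.append(peak)
                open_i = -1
            slow += a_slow_below * (e[i] - slow)
        slow = max(slow, 1e-300)
    if open_i >= 0:
        starts.append(open_i)
        ends.append(len(e))
        peaks.append(peak)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64), np.array(peaks)


try:  # numba makes the sample-by-sample tracker practical on hour-long files
    import numba

    _dual_ema_events = numba.njit(cache=True, nogil=True)(_dual_ema_events_py)
except ImportError:  # pragma: no cover - numba is expected in the environment
    _dual_ema_events = _dual_ema_events_py


def click_detect(
    segment: CalibratedSegment,
    threshold: float = CLICK_THRESHOLD_DB,
    fast_alpha: float = CLICK_FAST_ALPHA,
    slow_alpha_below: float = CLICK_SLOW_ALPHA_BELOW,
    slow_alpha_above: float = CLICK_SLOW_ALPHA_ABOVE,
) -> list[TransientDetection]:
    """Detect short broadband transients (clicks).

    The signal is high-passed at 3000 Hz and squared; a detection opens
    while the fast moving average exceeds the slow (noise) average by the
    threshold (default 12 dB) and closes when it falls below. Events
    separated by less than 2 ms are merged; events outside the
    0.1–50 ms duration range are discarded (the click path is unsuited
    for longer impulsive sounds).
    """
    fs = segment.sample_rate
    if fs < 8192:
        raise ValueError("click detection requires sample rate ≥ 8192 Hz")
    sos = signal.butter(4, CLICK_HIGHPASS_HZ, btype="high", fs=fs, output="sos")
    y = signal.sosfilt(sos, np.asarray(segment.pressure, dtype=np.float64))
    e = y * y
    n_init = min(len(e), fs)
    slow0 = float(np.mean(e[:n_init])) if n_init else 0.0
    if slow0 <= 0:
        return []
    thr_lin = 10.0 ** (threshold / 10.0)
    starts, ends, peaks = _dual_ema_events(
        e, thr_lin, fast_alpha, slow_alpha_below, slow_alpha_above, slow0)
    # merge events separated by < 2 ms
    merged: list[list[float]] = []
    gap = CLICK_MERGE_GAP_S * fs
    for s, t, p in zip(starts, ends, peaks):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = t
            merged[-1][2] = max(merged[-1][2], p)
        else:
            merged.append([s, t, p])
    out = []
    for s, t, p in merged:
        dur = (t - s) / fs
        if not (CLICK_MIN_DURATION_S <= dur <= CLICK_MAX_DURATION_S):
            continue
        out.append(TransientDetection(
            time=segment.start_time + pd.to_timedelta(s / fs, unit="s"),
            duration=dur,
            peak_snr=float(10.0 * np.log10(p)),
            detector="click",
            band=(CLICK_HIGHPASS_HZ, fs / 2.0),
        ))
    return out


def energy_sum_detect(
    lf_spec: SpectrogramBlock,
    threshold: float = ENERGY_SUM_THRESHOLD_DB,
    alpha: float = ENERGY_SUM_ALPHA,
    band: tuple[float, float] = ENERGY_SUM_BAND,
) -> list[TransientDetection]:
    """Detect longer low-frequency impulses from summed spectrogram energy.

    Per frame the energy E is the summed squared magnitude over the 0–600
    Hz bins of the (decimated-rate) spectrogram; a slow exponential
    background of E adapts with ``alpha`` while no detection is open (and
    ten times slower while one is). A detection spans the consecutive
    frames where 10·log10(E/background) exceeds the threshold (default
    8 dB).
    """
    mask = (lf_spec.bin_frequencies >= band[0]) & (lf_spec.bin_frequencies <= band[1])
    if not mask.any():
        raise ValueError("no spectrogram bins inside the analysis band")
    power = 10.0 ** (lf_spec.magnitude[:, mask].astype(np.float64) / 10.0)
    energy = power.sum(axis=1)
    n_seed = min(10, len(energy))
    bkg = float(np.median(energy[:n_seed]))
    bkg = max(bkg, 1e-300)
    thr_lin = 10.0 ** (threshold / 10.0)
    events: list[list[float]] = []  # [i0, i1, peak_ratio]
    open_i = -1
    peak = 0.0
    for i, e_i in enumerate(energy):
        above = e_i > thr_lin * bkg
        if above:
            if open_i < 0:
                open_i, peak = i, e_i / bkg
            else:
                peak = max(peak, e_i / bkg)
            bkg += (alpha / 10.0) * (e_i - bkg)
        else:
            if open_i >= 0:
                events.append([open_i, i, peak])
                open_i = -1
            bkg += alpha * (e_i - bkg)
        bkg = max(bkg, 1e-300)
    if open_i >= 0:
        events.append([open_i, len(energy), peak])
    # merge events split by ≤ 2 below-threshold frames (dropouts inside a pulse)
    merged: list[list[float]] = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] <= 2:
            merged[-1][1] = ev[1]
            merged[-1][2] = max(merged[-1][2], ev[2])
        else:
            merged.append(ev)
    fs = lf_spec.sample_rate
    base = lf_spec.start_time if lf_spec.start_time is not None else pd.Timestamp(0)
    out = []
    for i0, i1, pk in merged:
        i0, i1 = int(i0), int(i1)
        if i1 - i0 < ENERGY_SUM_MIN_FRAMES:
            continue
        # energy-weighted centroid gives sub-frame timing, so pulse-train
        # interval statistics are not quantised by the hop length
        frames = np.arange(i0, i1)
        w = energy[i0:i1]
        t_c = float(np.sum(w * lf_spec.frame_times[frames]) / np.sum(w))
        out.append(TransientDetection(
            time=base + pd.to_timedelta(t_c, unit="s"),
            duration=(i1 - i0) * lf_spec.hop / fs,
            peak_snr=float(10.0 * np.log10(pk)),
            detector="energy_sum",
            band=band,
        ))
    return out


def detections_to_records(detections: list[TransientDetection]) -> list[dict]:
    """JSON-serialisable records, one per detection."""
    return [
        {
            "time": d.time.isoformat(),
            "duration": round(d.duration, 6),
            "peak_snr": round(d.peak_snr, 3),
            "detector": d.detector,
            "band": list(d.band),
        }
        for d in detections
    ]
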