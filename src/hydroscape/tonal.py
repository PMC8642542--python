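"""Generic tonal-sound detection (whistles and moans).

Long narrowband sounds — baleen-whale moans and seal calls below 1500 Hz,
toothed-whale whistles above — are detected on a spectrogram by estimating
a slowly adapting per-bin background, thresholding the excess to a binary
image, and extracting time-frequency ridges as connected components. Two
paths mirror the two frequency scales: the HF path runs at the native
sampling rate with a 1024-point FFT (512 hop), the LF path first low-pass
filters (4-pole Butterworth, 1500 Hz) and decimates to 3000 Hz, then uses
a 512-point FFT (256 hop); both use Hann windows. At 3000 Hz the LF bin
width is 3000/512 = 5.86 Hz; at 32768 Hz the HF bin width is 32 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from hydroscape.calibration import CalibratedSegment

LF_RATE = 3000
LF_FFT, LF_HOP = 512, 256
HF_FFT, HF_HOP = 1024, 512
SPLIT_HZ = 1500.0
BACKGROUND_ALPHA = 0.02
BINARIZE_THRESHOLD_DB = 8.0
MAX_BIN_JUMP = 2
MIN_DURATION_S = {"LF_moan": 0.30, "HF_whistle": 0.15}
SMOOTH_FRAMES = {"LF": 3, "HF": 5}  # HF frames are shorter; match ~min duration/2
MIN_FREQ_HZ = 10.0  # analysis floor; DC-adjacent bins carry filter roll-off only
_EPS = 1e-12


@dataclass
class SpectrogramBlock:
    """Magnitude spectrogram (dB) of one contiguous segment."""

    frame_times: np.ndarray          # seconds from segment start (frame starts)
    bin_frequencies: np.ndarray      # Hz
    magnitude: np.ndarray            # dB, frames × bins
    fft_length: int
    hop: int
    sample_rate: int
    start_time: pd.Timestamp | None = None


@dataclass
class TonalContour:
    """A detected tonal sound as a time-frequency ridge."""

    start_time: pd.Timestamp
    duration: float
    contour: list[tuple[float, float]]   # (seconds from start_time, Hz)
    min_freq: float
    max_freq: float
    mean_snr: float
    detector: str                        # LF_moan | HF_whistle


def decimate_lf(segment: CalibratedSegment) -> CalibratedSegment:
    """Low-pass (4-pole Butterworth, 1500 Hz) and resample to 3000 Hz.

    The standard logger rates (8192/16384/32768 Hz) are handled by
    polyphase rational resampling after the anti-alias filter.
    """
    fs = segment.sample_rate
    if fs < LF_RATE:
        raise ValueError(f"sample rate {fs} Hz below target {LF_RATE} Hz")
    if fs == LF_RATE:
        return segment
    sos = signal.butter(4, SPLIT_HZ, btype="low", fs=fs, output="sos")
    y = signal.sosfilt(sos, np.asarray(segment.pressure, dtype=np.float64))
    frac = Fraction(LF_RATE, fs)
    y = signal.resample_poly(y, frac.numerator, frac.denominator)
    return replace(segment, pressure=y, sample_rate=LF_RATE)


def spectrogram(
    segment: CalibratedSegment,
    fft_length: int,
    hop: int | None = None,
) -> SpectrogramBlock:
    """Hann-window magnitude spectrogram with 50% overlap by default."""
    hop = fft_length // 2 if hop is None else hop
    fs = segment.sample_rate
    x = np.asarray(segment.pressure, dtype=np.float32)
    f, t, z = signal.stft(
        x, fs=fs, window="hann", nperseg=fft_length, noverlap=fft_length - hop,
        boundary=None, padded=False)
    mag = 20.0 * np.log10(np.abs(z).T + _EPS)
    frame_times = t - (fft_length / 2) / fs  # stft centres; convert to frame starts
    return SpectrogramBlock(
        frame_times=frame_times.astype(float),
        bin_frequencies=f.astype(float),
        magnitude=mag.astype(np.float32),
        fft_length=fft_length,
        hop=hop,
        sample_rate=fs,
        start_time=segment.start_time,
    )


def running_background(
    magnitude: np.ndarray,
    alpha: float = BACKGROUND_ALPHA,
    seed_frames: int = 10,
) -> np.ndarray:
    """Per-bin exponentially decaying background estimate (dB).

    B(t) = (1−α)·B(t−1) + α·mag(t), seeded with the median of the first
    ``seed_frames`` frames. Returns the background *before* each frame's
    update, so a frame is compared against its own past only.
    """
    mag = np.asarray(magnitude, dtype=np.float64)
    b0 = np.median(mag[:seed_frames], axis=0)
    zi = ((1 - alpha) * b0)[None, :]
    b = signal.lfilter([alpha], [1.0, -(1 - alpha)], mag, axis=0, zi=zi)[0]
    prev = np.empty_like(b)
    prev[0] = b0
    prev[1:] = b[:-1]
    return prev


def excess_map(
    spec: SpectrogramBlock,
    alpha: float = BACKGROUND_ALPHA,
    smooth_frames: int = 3,
) -> np.ndarray:
    """Noise-reduced excess (dB) over the adaptive background.

    The raw dB excess of Gaussian noise has a ~5.6 dB per-pixel spread, so
    thresholding it directly chains chance pixels into spurious contours.
    A short moving average along time (the noise-reduction step) shrinks
    the noise spread by ~√smooth_frames while leaving any signal that
    persists across frames — the defining property of a tonal — intact.
    """
    excess = spec.magnitude - running_background(spec.magnitude, alpha)
    if smooth_frames > 1:
        excess = ndimage.uniform_filter1d(excess, smooth_frames, axis=0)
    return excess


def whiten_binarize(
    spec: SpectrogramBlock,
    threshold: float = BINARIZE_THRESHOLD_DB,
    alpha: float = BACKGROUND_ALPHA,
    smooth_frames: int = 3,
) -> np.ndarray:
    """Binary detection image: smoothed excess over the background > threshold."""
    if spec.magnitude.shape[0] < 10:
        raise ValueError("need at least 10 spectrogram frames")
    return excess_map(spec, alpha, smooth_frames) > threshold


def extract_contours(
    binary_map: np.ndarray,
    spec: SpectrogramBlock,
    detector: str = "HF_whistle",
    min_duration: float | None = None,
    max_bin_jump: int = MAX_BIN_JUMP,
    excess_db: np.ndarray | None = None,
) -> list[TonalContour]:
    """Connected-component contour extraction from a binary spectrogram.

    Pixels in adjacent frames connect when their frequency bins differ by
    at most ``max_bin_jump``; per frame the contour frequency is the
    magnitude-weighted centroid of the component's bins. Components
    shorter than ``min_duration``, spanning fewer than 2 distinct bins, or
    averaging fewer than 2 pixels per frame are discarded — a genuine
    tonal always paints at least its analysis-window mainlobe (2 bins),
    whereas chance chains in smoothed noise are single-pixel threads.
    """
    if min_duration is None:
        min_duration = MIN_DURATION_S[detector]
    if excess_db is None:
        excess_db = excess_map(spec)
    fs = spec.sample_rate
    # Dilating along frequency by max_bin_jump, then labelling with full
    # (8-)connectivity, links pixels in adjacent frames whose bins differ
    # by ≤ max_bin_jump (and same-frame neighbours).
    dilated = ndimage.binary_dilation(
        binary_map, structure=np.ones((1, 2 * max_bin_jump + 1), dtype=bool))
    labels, n_labels = ndimage.label(dilated, structure=np.ones((3, 3), dtype=int))
    labels = np.where(binary_map, labels, 0)
    contours: list[TonalContour] = []
    base_time = spec.start_time if spec.start_time is not None else pd.Timestamp(0)
    min_frames = int(np.ceil(min_duration * fs / spec.hop))
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        if sl[0].stop - sl[0].start < min_frames:
            continue
        sub = labels[sl] == lab
        fr, bins = np.nonzero(sub)
        if fr.size == 0:
            continue
        fr = fr + sl[0].start
        bins = bins + sl[1].start
        if np.unique(bins).size < 2:
            continue
        f0, f1 = fr.min(), fr.max()
        duration = (f1 - f0 + 1) * spec.hop / fs
        if duration < min_duration:
            continue
        if fr.size < 2 * (f1 - f0 + 1):
            continue
        pts = []
        for frame in range(f0, f1 + 1):
            sel = bins[fr == frame]
            if sel.size == 0:
                continue
            w = 10.0 ** (spec.magnitude[frame, sel].astype(np.float64) / 10.0)
            freq = float(np.sum(w * spec.bin_frequencies[sel]) / np.sum(w))
            pts.append((float(spec.frame_times[frame]), freq))
        freqs = [p[1] for p in pts]
        snr = float(np.mean(excess_db[fr, bins]))
        t_first = pts[0][0]
        contours.append(TonalContour(
            start_time=base_time + pd.to_timedelta(t_first, unit="s"),
            duration=float(duration),
            contour=[(t - t_first, f) for t, f in pts],
            min_freq=float(np.min(freqs)),
            max_freq=float(np.max(freqs)),
            mean_snr=snr,
            detector=detector,
        ))
    contours.sort(key=lambda c: c.start_time)
    return contours


def detect_tonals(
    segment: CalibratedSegment,
    path: str = "LF",
    threshold: float = BINARIZE_THRESHOLD_DB,
    min_duration: float | None = None,
) -> list[TonalContour]:
    """Run one tonal detection path over a calibrated segment.

    ``path='HF'`` searches 1500 Hz–Nyquist on the native-rate spectrogram
    (FFT 1024, hop 512); ``path='LF'`` decimates to 3000 Hz first and
    searches below 1500 Hz (FFT 512, hop 256).
    """
    if path == "HF":
        if segment.sample_rate <= LF_RATE:
            raise ValueError("HF path requires sample rate > 3000 Hz")
        spec = spectrogram(segment, HF_FFT, HF_HOP)
        band_mask = spec.bin_frequencies >= SPLIT_HZ
        detector = "HF_whistle"
    elif path == "LF":
        spec = spectrogram(decimate_lf(segment), LF_FFT, LF_HOP)
        band_mask = ((spec.bin_frequencies < SPLIT_HZ)
                     & (spec.bin_frequencies >= MIN_FREQ_HZ))
        detector = "LF_moan"
    else:
        raise ValueError("path must be 'LF' or 'HF'")
    excess = excess_map(spec, smooth_frames=SMOOTH_FRAMES[path])
    binary = (excess > threshold) & band_mask[None, :]
    return extract_contours(binary, spec, detector=detector,
                            min_duration=min_duration, excess_db=excess)


def contours_to_records(contours: list[TonalContour]) -> list[dict]:
    """JSON-serialisable records, one per contour."""
    return [
        {
            "start": c.start_time.isoformat(),
            "duration": c.duration,
            "contour": [[round(t, 6), round(f, 3)] for t, f in c.contour],
            "min_freq": c.min_freq,
            "max_freq": c.max_freq,
            "mean_snr": c.mean_snr,
            "detector": c.detector,
        }
        for c in contours
    ]
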