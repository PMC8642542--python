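"""Reading, calibrating and time-managing autonomous hydrophone recordings.

An autonomous logger stores 16-bit digital counts; the calibration contract
maps digital full scale (±32768 counts) to the system *peak* clipping level
in dB re 1 µPa, so that pressure in µPa is ``raw / 32768 · 10^(clip/20)``.
Absolute time comes from a sidecar manifest (ISO-8601 timestamps), never
from WAV headers; duty-cycle gaps are represented as absent segments and
are never zero-filled, so they cannot bias RMS statistics.
"""

from __future__ import annotations

import struct
import warnings
import wave
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FULL_SCALE = 32768  # counts at digital full scale (16-bit)

STANDARD_RATES = (8192, 16384, 32768)


class WavFormatError(ValueError):
    """Raised when a WAV file is not mono 16-bit RIFF PCM or is truncated."""


@dataclass(frozen=True)
class DeploymentMetadata:
    """Static per-deployment recording metadata.

    Parameters
    ----------
    station_id : str
        Station label.
    sample_rate : int
        Sampling rate in Hz. Rates other than 8192/16384/32768 Hz are
        accepted with a warning.
    sensitivity : float
        Hydrophone sensitivity, dB re 1 V/µPa (informational; the digital
        chain is calibrated through ``clip_level_peak``).
    clip_level_peak : float
        System peak clipping level, dB re 1 µPa. Digital full scale maps
        to this peak pressure.
    duty_cycle : tuple[float, float] | None
        (record minutes, cycle minutes), or None for continuous recording.
    deployment_start, deployment_end : pandas.Timestamp
        UTC deployment window; ``deployment_end > deployment_start``.
    recorder_depth : float | None
        Recorder depth in metres (informational).
    """

    station_id: str
    sample_rate: int
    sensitivity: float = -165.0
    clip_level_peak: float = 151.0
    duty_cycle: tuple[float, float] | None = None
    deployment_start: pd.Timestamp | None = None
    deployment_end: pd.Timestamp | None = None
    recorder_depth: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.clip_level_peak):
            raise ValueError("clip_level_peak must be finite")
        if self.sample_rate not in STANDARD_RATES:
            warnings.warn(
                f"sample rate {self.sample_rate} Hz is not one of the standard "
                f"rates {STANDARD_RATES}", stacklevel=2)
        if (self.deployment_start is not None and self.deployment_end is not None
                and not self.deployment_end > self.deployment_start):
            raise ValueError("deployment_end must be after deployment_start")

    @property
    def full_scale_pressure(self) -> float:
        """Peak pressure at digital full scale, µPa."""
        return 10.0 ** (self.clip_level_peak / 20.0)


@dataclass
class CalibratedSegment:
    """A contiguous calibrated pressure time series.

    ``pressure`` is in µPa, ``start_time`` is the UTC time of sample 0 and
    ``clipped_fraction`` is the fraction of samples that sat at digital
    full scale before calibration.
    """

    pressure: np.ndarray
    start_time: pd.Timestamp
    sample_rate: int
    clipped_fraction: float = 0.0
    station_id: str = ""

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self.pressure) / self.sample_rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.to_timedelta(self.duration, unit="s")

    def slice_time(self, t0: pd.Timestamp, t1: pd.Timestamp) -> "CalibratedSegment":
        """Return the sub-segment overlapping the half-open window [t0, t1)."""
        i0 = int(np.ceil(max((t0 - self.start_time).total_seconds(), 0.0)
                         * self.sample_rate))
        i1 = int(np.ceil(max((t1 - self.start_time).total_seconds(), 0.0)
                         * self.sample_rate))
        i1 = min(i1, len(self.pressure))
        i0 = min(i0, i1)
        return replace(
            self,
            pressure=self.pressure[i0:i1],
            start_time=self.start_time + pd.to_timedelta(i0 / self.sample_rate, unit="s"),
        )


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono 16-bit RIFF PCM WAV file.

    Returns ``(samples, sample_rate)`` with samples as int16 in
    [−32768, 32767]. Multichannel, non-PCM or truncated files raise
    :class:`WavFormatError` naming the defect.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as w:
            n_channels = w.getnchannels()
            sampwidth = w.getsampwidth()
            rate = w.getframerate()
            n_frames = w.getnframes()
            if n_channels != 1:
                raise WavFormatError(
                    f"{path.name}: expected 1 channel, found {n_channels}")
            if sampwidth != 2:
                raise WavFormatError(
                    f"{path.name}: expected 16-bit PCM, found {8 * sampwidth}-bit")
            if n_frames == 0:
                raise WavFormatError(f"{path.name}: empty payload")
            data = w.readframes(n_frames)
    except wave.Error as exc:  # compressed / malformed RIFF
        raise WavFormatError(f"{path.name}: not a readable PCM WAV ({exc})") from exc
    except (EOFError, struct.error) as exc:
        raise WavFormatError(f"{path.name}: truncated file ({exc})") from exc
    if len(data) < 2 * n_frames:
        raise WavFormatError(
            f"{path.name}: truncated payload "
            f"({len(data)} bytes for {n_frames} declared frames)")
    samples = np.frombuffer(data, dtype="<i2")
    return samples, rate


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write int16 samples as a mono 16-bit RIFF PCM WAV file."""
    samples = np.asarray(samples, dtype="<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(sample_rate))
        w.writeframes(samples.tobytes())


def calibrate(
    raw_samples: np.ndarray,
    meta: DeploymentMetadata,
    start_time: pd.Timestamp | None = None,
) -> CalibratedSegment:
    """Convert digital counts into calibrated pressure in µPa.

    pressure = raw / 32768 × 10^(clip_level_peak / 20); the clipped
    fraction counts samples with \\|raw\\| ≥ 32767. The mapping is linear
    and invertible for non-clipped samples.
    """
    raw = np.asarray(raw_samples)
    pressure = raw.astype(np.float64) / FULL_SCALE * meta.full_scale_pressure
    clipped = float(np.mean(np.abs(raw.astype(np.int64)) >= FULL_SCALE - 1)) if raw.size else 0.0
    return CalibratedSegment(
        pressure=pressure,
        start_time=pd.Timestamp("1970-01-01") if start_time is None else pd.Timestamp(start_time),
        sample_rate=meta.sample_rate,
        clipped_fraction=clipped,
        station_id=meta.station_id,
    )


def uncalibrate(segment: CalibratedSegment, clip_level_peak: float = 151.0) -> np.ndarray:
    """Inverse of :func:`calibrate`: pressure in µPa back to int16 counts.

    Values beyond digital full scale are hard-clipped.
    """
    full_scale = 10.0 ** (clip_level_peak / 20.0)
    counts = np.round(segment.pressure / full_scale * FULL_SCALE)
    return np.clip(counts, -FULL_SCALE, FULL_SCALE - 1).astype(np.int16)


def trim_deployment(
    segments: list[CalibratedSegment],
    meta: DeploymentMetadata,
    guard: pd.Timedelta | float = pd.Timedelta(hours=24),
) -> list[CalibratedSegment]:
    """Drop or truncate audio within ``guard`` of the deployment edges.

    The first and last guard interval of a deployment are contaminated by
    the deploying vessel; audio overlapping those windows is removed
    (segments straddling a boundary are truncated). A deployment shorter
    than twice the guard yields an empty list with a warning.
    """
    if not isinstance(guard, pd.Timedelta):
        guard = pd.to_timedelta(guard, unit="s")
    if meta.deployment_start is None or meta.deployment_end is None:
        raise ValueError("deployment window required for trimming")
    keep_start = meta.deployment_start + guard
    keep_end = meta.deployment_end - guard
    if keep_end <= keep_start:
        warnings.warn(
            f"deployment {meta.station_id} shorter than twice the guard "
            f"({guard}); nothing retained", stacklevel=2)
        return []
    out = []
    for seg in segments:
        clipped = seg.slice_time(max(seg.start_time, keep_start),
                                 min(seg.end_time, keep_end))
        if len(clipped.pressure):
            out.append(clipped)
    return out
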