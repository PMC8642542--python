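"""Synthetic hydrophone scenes with exact ground truth.

Generates calibrated single-channel audio with the statistical structure a
long-term Arctic soundscape analysis assumes: coloured Gaussian ambient
noise at user-set decade-band levels, tidal (~6/12-h) amplitude modulation
of the low-frequency component, a recorder self-noise floor, and injected
events — seismic airgun pulse trains with reverberant tails and fixed
inter-pulse intervals, down-swept tonal calls (bearded-seal-like),
low-frequency moans, broadband clicks and pure tones. Every injected event
is logged exactly, so detector recall and false-alarm rates can be
measured against known truth. Identical (spec, seed) pairs produce
byte-identical audio.

Event SNR is defined as the event's RMS band level minus the ambient band
level in the event's occupied third-octave range, over the event duration
— matching how the detectors' relative thresholds operate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from hydroscape.calibration import (
    CalibratedSegment,
    DeploymentMetadata,
    calibrate,
    uncalibrate,
    write_wav,
)

DEFAULT_CLIP_DB = 151.0
DEFAULT_AMBIENT = {"VLF": 100.0, "LF": 95.0, "MF": 85.0}
DEFAULT_SLOPE_DB_PER_DECADE = -14.0
SEMIDIURNAL_TIDE_H = 12.42

_DECADE_EDGES = {"VLF": (10.0, 100.0), "LF": (100.0, 1000.0), "MF": (1000.0, 10000.0)}


@dataclass
class EventSpec:
    """One injected event: type, onset (s) and type-specific parameters."""

    type: str  # airgun_train | downsweep | moan | click | tone
    onset: float
    params: dict = field(default_factory=dict)


@dataclass
class SceneSpec:
    """Declarative synthetic scene."""

    duration: float = 60.0
    sample_rate: int = 8192
    ambient: dict = field(default_factory=lambda: dict(DEFAULT_AMBIENT))
    spectral_slope: float = DEFAULT_SLOPE_DB_PER_DECADE
    tidal_modulation: tuple[float, float, float] | None = None  # (period h, depth dB, ceiling Hz)
    self_noise_floor: dict | None = None  # nominal band centre Hz -> dB
    events: list[EventSpec] = field(default_factory=list)
    seed: int = 0
    clip_level_peak: float = DEFAULT_CLIP_DB
    station_id: str = "SYN"
    start_time: str = "2019-06-01T00:00:00"

    def __post_init__(self) -> None:
        for ev in self.events:
            if not 0 <= ev.onset <= self.duration:
                raise ValueError(f"event onset {ev.onset}s outside scene duration")


@dataclass
class GroundTruthEvent:
    """Exact log record of one injected event."""

    type: str
    onset: float
    duration: float
    f_lo: float
    f_hi: float
    snr: float
    pulse_times: list[float] | None = None

    def to_dict(self) -> dict:
        d = {
            "type": self.type,
            "onset": round(self.onset, 6),
            "duration": round(self.duration, 6),
            "f_lo": round(self.f_lo, 3),
            "f_hi": round(self.f_hi, 3),
            "snr": self.snr,
        }
        if self.pulse_times is not None:
            d["pulse_times"] = [round(t, 6) for t in self.pulse_times]
        return d


def _band_weights(n: int) -> np.ndarray:
    """Per-rfft-bin weights such that mean square = Σ w·|X_k|²."""
    m = n // 2 + 1
    w = np.full(m, 2.0 / n**2)
    w[0] = 1.0 / n**2
    if n % 2 == 0:
        w[-1] = 1.0 / n**2
    return w


def gen_ambient(
    duration: float,
    sample_rate: int,
    decade_levels: dict | None = None,
    spectral_slope: float = DEFAULT_SLOPE_DB_PER_DECADE,
    seed: int | np.random.SeedSequence = 0,
    clip_level_peak: float = DEFAULT_CLIP_DB,
) -> np.ndarray:
    """Coloured Gaussian ambient noise, µPa, exact decade-band levels.

    White Gaussian noise is shaped in the frequency domain to the
    requested power-spectral slope (dB/decade), then each decade band's
    coefficients are rescaled so the realised RMS band level equals its
    target exactly; bins outside 10 Hz–10 kHz follow the nearest decade's
    scaling. Targets within 6 dB of the clip level are refused.
    """
    decade_levels = dict(DEFAULT_AMBIENT) if decade_levels is None else decade_levels
    for label, level in decade_levels.items():
        if level > clip_level_peak - 6.0:
            raise ValueError(
                f"{label} target {level} dB within 6 dB of clip level {clip_level_peak}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    f_floor = 5.0
    f_eff = np.maximum(freqs, f_floor)
    gain = (f_eff / 100.0) ** (spectral_slope / 20.0)
    gain[0] = 0.0
    spec = spec * gain
    w = _band_weights(n)
    # nearest specified decade per bin (log-frequency distance)
    labels = list(decade_levels)
    centres = np.array([np.sqrt(lo * hi) for lo, hi in
                        (_DECADE_EDGES[lb] for lb in labels)])
    with np.errstate(divide="ignore"):
        logf = np.log10(np.maximum(freqs, 1e-3))
    nearest = np.argmin(np.abs(logf[:, None] - np.log10(centres)[None, :]), axis=1)
    factors = np.ones(len(freqs))
    for j, label in enumerate(labels):
        lo, hi = _DECADE_EDGES[label]
        in_band = (freqs >= lo) & (freqs < hi)
        target_rms = 10.0 ** (decade_levels[label] / 20.0)
        measured = np.sqrt(np.sum(w[in_band] * np.abs(spec[in_band]) ** 2))
        if measured <= 0:
            raise ValueError(f"no spectral support in decade {label}")
        scale = target_rms / measured
        factors[in_band] = scale
        outside = (nearest == j) & ~((freqs >= 10.0) & (freqs < 10000.0))
        factors[outside] = scale
    return np.fft.irfft(spec * factors, n=n)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def gen_airgun_train(
    ipi: float,
    n_pulses: int,
    jitter: float = 0.0,
    snr: float = 15.0,
    centre: float = 150.0,
    tail: float = 0.4,
    sample_rate: int = 8192,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, list[float]]:
    """Airgun-like pulse train: band-limited pulses with exponential tails.

    Each pulse is Gaussian noise under an ``exp(−t/tail)`` envelope,
    band-passed around ``centre`` Hz (one octave either side), normalised
    to unit RMS over its first 3 time constants. Pulse k starts at
    ``k·ipi + U(−jitter, jitter)``. Returns (audio at unit per-pulse RMS,
    exact pulse start times). The ``snr`` is applied at scene-render time
    relative to the local ambient band level.
    """
    if ipi <= tail:
        raise ValueError("inter-pulse interval must exceed the pulse tail")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    pulse_len = int(round(6 * tail * fs))
    t = np.arange(pulse_len) / fs
    # steep band-pass keeps the pulse confined to its stated band, so the
    # tonal detectors are not triggered by out-of-band skirts
    sos = signal.butter(4, [centre / 2.0, centre * 2.0], btype="bandpass",
                        fs=fs, output="sos")
    times = [max(k * ipi + (rng.uniform(-jitter, jitter) if jitter else 0.0), 0.0)
             for k in range(n_pulses)]
    total = int(round((max(times) + 6 * tail) * fs)) + 1
    audio = np.zeros(total)
    core = slice(0, int(round(3 * tail * fs)))
    for t0 in times:
        pulse = signal.sosfilt(sos, rng.standard_normal(pulse_len) * np.exp(-t / tail))
        pulse = pulse / np.sqrt(np.mean(pulse[core] ** 2))
        i0 = int(round(t0 * fs))
        audio[i0: i0 + pulse_len] += pulse[: len(audio) - i0]
    return audio, times


def gen_downsweep(
    f_start: float,
    f_end: float,
    duration: float,
    sample_rate: int = 8192,
    snr: float = 15.0,
) -> np.ndarray:
    """Down-swept tonal call: linear-in-log frequency, Hann envelope.

    The instantaneous frequency is ``f_start · (f_end/f_start)^(t/T)``, so
    the mid-point frequency is the geometric mean √(f_start·f_end).
    Returned at unit RMS (silent if ``snr`` weight is exactly 0); the SNR
    scaling happens at render time.
    """
    if not f_start > f_end > 0:
        raise ValueError("downsweep requires f_start > f_end > 0")
    fs = sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ratio = f_end / f_start
    phase = 2 * np.pi * f_start * duration / np.log(ratio) * (ratio ** (t / duration) - 1)
    x = np.sin(phase) * np.hanning(n)
    if snr == 0:
        return np.zeros(n)
    return _unit_rms(x)


def gen_moan(
    freq: float = 50.0,
    duration: float = 1.0,
    sample_rate: int = 8192,
    vibrato_hz: float = 2.0,
    vibrato_depth: float = 2.0,
) -> np.ndarray:
    """Low-frequency moan: near-constant tone with slight vibrato, Hann envelope."""
    fs = sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    inst_f = freq + vibrato_depth * np.sin(2 * np.pi * vibrato_hz * t)
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    return _unit_rms(np.sin(phase) * np.hanning(n))


def gen_click(
    duration: float = 5e-4,
    sample_rate: int = 8192,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Broadband click: short high-passed noise burst under a Hann envelope."""
    rng = np.random.default_rng(seed)
    fs = sample_rate
    n = max(int(round(duration * fs)), 4)
    sos = signal.butter(2, min(3000.0, 0.4 * fs), btype="high", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n)) * np.hanning(n)
    return _unit_rms(x)


def gen_tone(freq: float, duration: float, sample_rate: int = 8192) -> np.ndarray:
    """Pure tone at unit RMS with a Hann envelope."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return _unit_rms(np.sin(2 * np.pi * freq * t) * np.hanning(n))


def _event_band(ev: EventSpec, fs: int) -> tuple[float, float]:
    p = ev.params
    if ev.type == "airgun_train":
        c = p.get("centre", 150.0)
        return c / 2.0, c * 2.0
    if ev.type == "downsweep":
        return p["f_end"], p["f_start"]
    if ev.type == "moan":
        f = p.get("freq", 50.0)
        return 0.7 * f, 1.4 * f
    if ev.type == "click":
        return 3000.0, fs / 2.0
    if ev.type == "tone":
        f = p["freq"]
        return 0.9 * f, 1.1 * f
    raise ValueError(f"unknown event type {ev.type!r}")


def _ambient_band_rms(mixture: np.ndarray, fs: int, f_lo: float, f_hi: float,
                      i0: int, n: int) -> float:
    """RMS of the background in [f_lo, f_hi] around sample i0."""
    f_hi = min(f_hi, 0.45 * fs)
    f_lo = max(min(f_lo, 0.8 * f_hi), 1.0)
    pad = n  # settle the filter on the preceding stretch
    j0 = max(i0 - pad, 0)
    sl = mixture[j0: i0 + n]
    sos = signal.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, sl)[-n:]
    return float(np.sqrt(np.mean(y**2)))


def render_scene(
    spec: SceneSpec,
) -> tuple[CalibratedSegment, list[GroundTruthEvent], dict]:
    """Render a scene to a calibrated segment plus its exact event log.

    Sums ambient noise, tidal modulation (a slow multiplicative gain on
    the component below the stated ceiling), an optional self-noise floor
    (additive stationary band-limited noise at the stated third-octave
    levels) and the events, each scaled to its stated SNR relative to the
    local ambient level in the event's occupied band. The waveform is
    quantised through the 16-bit calibration inverse, so the returned
    segment is exactly what reading the written WAV would give; summed
    signal beyond the clip level is hard-clipped and logged.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(len(spec.events) + 2)
    mix = gen_ambient(spec.duration, fs, spec.ambient, spec.spectral_slope,
                      seed=child[0], clip_level_peak=spec.clip_level_peak)

    if spec.tidal_modulation is not None:
        period_h, depth_db, ceiling = spec.tidal_modulation
        sos = signal.butter(4, ceiling, btype="low", fs=fs, output="sos")
        low = signal.sosfilt(sos, mix)
        t = np.arange(n) / fs
        gain = 10.0 ** (depth_db * np.sin(2 * np.pi * t / (3600.0 * period_h)) / 20.0)
        mix = low * gain + (mix - low)

    if spec.self_noise_floor:
        rng_sn = np.random.default_rng(child[1])
        for centre, level in spec.self_noise_floor.items():
            centre = float(centre)
            lo, hi = centre * 2 ** (-1 / 6), centre * 2 ** (1 / 6)
            if hi >= 0.95 * fs / 2:
                continue
            # brick-wall band noise with exact in-band RMS, so a
            # third-octave measurement recovers the stated floor level
            spec_sn = np.fft.rfft(rng_sn.standard_normal(n))
            freqs = np.fft.rfftfreq(n, 1.0 / fs)
            in_band = (freqs >= lo) & (freqs < hi)
            spec_sn[~in_band] = 0.0
            w = _band_weights(n)
            rms = np.sqrt(np.sum(w[in_band] * np.abs(spec_sn[in_band]) ** 2))
            mix = mix + np.fft.irfft(spec_sn, n=n) * (10.0 ** (level / 20.0) / rms)

    truth: list[GroundTruthEvent] = []
    for k, ev in enumerate(spec.events):
        p = dict(ev.params)
        snr = p.get("snr", 15.0)
        f_lo, f_hi = _event_band(ev, fs)
        pulse_times = None
        if ev.type == "airgun_train":
            audio, rel_times = gen_airgun_train(
                ipi=p.get("ipi", 12.0), n_pulses=p.get("n_pulses", 15),
                jitter=p.get("jitter", 0.0), snr=snr,
                centre=p.get("centre", 150.0), tail=p.get("tail", 0.4),
                sample_rate=fs, seed=child[k + 2])
            pulse_times = [ev.onset + t for t in rel_times]
            duration = len(audio) / fs
        elif ev.type == "downsweep":
            audio = gen_downsweep(p["f_start"], p["f_end"], p.get("duration", 2.0),
                                  fs, snr=snr)
            duration = len(audio) / fs
        elif ev.type == "moan":
            audio = gen_moan(p.get("freq", 50.0), p.get("duration", 1.0), fs)
            duration = len(audio) / fs
        elif ev.type == "click":
            audio = gen_click(p.get("duration", 5e-4), fs, seed=child[k + 2])
            duration = len(audio) / fs
        elif ev.type == "tone":
            audio = gen_tone(p["freq"], p.get("duration", 1.0), fs)
            duration = len(audio) / fs
        else:
            raise ValueError(f"unknown event type {ev.type!r}")
        i0 = int(round(ev.onset * fs))
        n_ev = min(len(audio), n - i0)
        if n_ev <= 0:
            continue
        amb_rms = _ambient_band_rms(mix, fs, f_lo, f_hi, i0, n_ev)
        scale = amb_rms * 10.0 ** (snr / 20.0)
        if np.sqrt(np.mean(audio[:n_ev] ** 2)) > 0:
            mix[i0: i0 + n_ev] += audio[:n_ev] * scale
        truth.append(GroundTruthEvent(
            type=ev.type, onset=ev.onset, duration=duration,
            f_lo=f_lo, f_hi=f_hi, snr=snr, pulse_times=pulse_times))

    meta = scene_metadata(spec)
    raw = uncalibrate(
        CalibratedSegment(mix, pd.Timestamp(spec.start_time), fs),
        clip_level_peak=spec.clip_level_peak)
    segment = calibrate(raw, meta, start_time=pd.Timestamp(spec.start_time))
    manifest = {
        "station": spec.station_id,
        "sample_rate": fs,
        "sensitivity": -165.0,
        "clip_level_peak": spec.clip_level_peak,
        "duty_cycle": None,
        "seed": spec.seed,
        "clipped_fraction": segment.clipped_fraction,
        "files": [{"path": f"{spec.station_id}.wav", "start_time": spec.start_time}],
    }
    return segment, truth, manifest


def scene_metadata(spec: SceneSpec) -> DeploymentMetadata:
    start = pd.Timestamp(spec.start_time)
    return DeploymentMetadata(
        station_id=spec.station_id,
        sample_rate=spec.sample_rate,
        clip_level_peak=spec.clip_level_peak,
        deployment_start=start,
        deployment_end=start + pd.to_timedelta(max(spec.duration, 1.0), unit="s"),
    )


def write_scene(spec: SceneSpec, outdir: str | Path) -> dict[str, Path]:
    """Render a scene and write WAV + ground-truth JSON + manifest YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segment, truth, manifest = render_scene(spec)
    raw = uncalibrate(segment, clip_level_peak=spec.clip_level_peak)
    wav_path = outdir / f"{spec.station_id}.wav"
    write_wav(wav_path, raw, spec.sample_rate)
    truth_path = outdir / f"{spec.station_id}_truth.json"
    truth_path.write_text(json.dumps({
        "events": [e.to_dict() for e in truth],
        "clipped_fraction": manifest["clipped_fraction"],
    }, indent=1))
    manifest_path = outdir / f"{spec.station_id}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest))
    return {"wav": wav_path, "truth": truth_path, "manifest": manifest_path}


def gen_hourly_tol_series(
    days: float = 30.0,
    base_db: float = 95.0,
    tidal_period_h: float | None = SEMIDIURNAL_TIDE_H,
    depth_db: float = 3.0,
    noise_sd_db: float = 1.0,
    seed: int = 0,
    start: str = "2019-01-01T00:00:00",
) -> pd.Series:
    """Hourly median-TOL series generated at the statistical level.

    Long-duration flow-noise periodogram scenarios (30 days of hourly
    medians) are generated directly as level series rather than as a
    month of audio — the periodogram consumes only hourly levels.
    """
    rng = np.random.default_rng(seed)
    n = int(round(days * 24))
    idx = pd.date_range(start, periods=n, freq="h")
    t = np.arange(n, dtype=float)
    levels = base_db + rng.normal(0.0, noise_sd_db, n)
    if tidal_period_h:
        levels = levels + depth_db * np.sin(2 * np.pi * t / tidal_period_h)
    return pd.Series(levels, index=idx, name="level_db")
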