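"""Pipeline orchestration: manifest in, reproducible product directory out.

Stages run in fixed order — calibrate → trim → band levels → QC →
detectors → seismic classification → summaries — over the WAV files
listed in a deployment manifest. Per-file failures are logged and the
file skipped; the effective configuration and a machine-readable run log
are written beside the products so a run can be regenerated exactly.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hydroscape import bands as bd
from hydroscape import calibration as cal
from hydroscape import qc as qcmod
from hydroscape import seismic as sc
from hydroscape import summaries as sm
from hydroscape import tonal as tn
from hydroscape import transient as tr

ALL_STAGES = ("bands", "qc", "detect", "seismic", "summarize")


@dataclass
class RunConfig:
    """Complete configuration for one pipeline run.

    Defaults follow the published analysis wherever it states a value
    (10-s TOL windows, 10 Hz lower band edge, detector thresholds 12/8 dB,
    IPI targets 12/14/18.5 ± 0.2 s, ≥ 15 pulses in 600 s, 24-h deployment
    guard). Unknown keys in a config file are rejected.
    """

    manifest: str = ""
    output_dir: str = "products"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    tol_window_s: float = 10.0
    band_fmin_nominal: float = 10.0
    band_fmax_nominal: float = 12500.0
    exceedance_percentages: tuple[int, ...] = bd.EXCEEDANCE_PERCENTAGES
    trim_guard_h: float = 24.0
    tonal_threshold_db: float = tn.BINARIZE_THRESHOLD_DB
    click_threshold_db: float = tr.CLICK_THRESHOLD_DB
    energy_sum_threshold_db: float = tr.ENERGY_SUM_THRESHOLD_DB
    seismic_targets_s: tuple[float, ...] = sc.IPI_TARGETS_S
    seismic_tol_s: float = sc.IPI_TOLERANCE_S
    seismic_min_run: int = sc.IPI_MIN_RUN
    seismic_run_window_s: float = sc.IPI_RUN_WINDOW_S
    seismic_window_s: float = 1800.0
    count_bin: str = "10min"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("stages", "exceedance_percentages", "seismic_targets_s"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d))


def _load_manifest(path: Path) -> tuple[cal.DeploymentMetadata, list[dict]]:
    data = yaml.safe_load(path.read_text())
    meta = cal.DeploymentMetadata(
        station_id=str(data.get("station", "station")),
        sample_rate=int(data["sample_rate"]),
        sensitivity=float(data.get("sensitivity", -165.0)),
        clip_level_peak=float(data.get("clip_level_peak", 151.0)),
        duty_cycle=tuple(data["duty_cycle"]) if data.get("duty_cycle") else None,
        deployment_start=pd.Timestamp(data["deployment_start"])
        if data.get("deployment_start") else None,
        deployment_end=pd.Timestamp(data["deployment_end"])
        if data.get("deployment_end") else None,
    )
    files = data["files"]
    base = path.parent
    for f in files:
        f["path"] = str((base / f["path"]).resolve())
    return meta, files


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the product directory.

    Raises ``RuntimeError`` if no products could be written at all.
    """
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def log_event(stage: str, **kw) -> None:
        log.append({"stage": stage, "elapsed_s": round(time.time() - t_start, 3), **kw})

    meta, files = _load_manifest(Path(config.manifest))
    band_list = bd.nominal_bands(config.band_fmin_nominal,
                                 min(config.band_fmax_nominal, meta.sample_rate / 2))

    tol_parts: list[bd.TOLSeries] = []
    tonal_records: list[dict] = []
    transient_records: list[dict] = []
    energy_detections: list[tr.TransientDetection] = []
    click_detections: list[tr.TransientDetection] = []
    recording_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []

    for f in files:
        try:
            raw, rate = cal.read_wav(f["path"])
            if rate != meta.sample_rate:
                raise cal.WavFormatError(
                    f"{f['path']}: rate {rate} differs from manifest "
                    f"{meta.sample_rate}")
            seg = cal.calibrate(raw, meta, start_time=pd.Timestamp(f["start_time"]))
        except (cal.WavFormatError, OSError, KeyError) as exc:
            log_event("calibrate", file=f.get("path"), error=str(exc))
            continue
        if meta.deployment_start is not None and meta.deployment_end is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trimmed = cal.trim_deployment(
                    [seg], meta, pd.Timedelta(hours=config.trim_guard_h))
            if not trimmed:
                log_event("trim", file=f["path"], dropped=True)
                continue
            seg = trimmed[0]
        recording_intervals.append((seg.start_time, seg.end_time))
        log_event("calibrate", file=f["path"], duration_s=seg.duration,
                  clipped_fraction=seg.clipped_fraction)

        if "bands" in config.stages or "qc" in config.stages or "summarize" in config.stages:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tol_parts.append(bd.tol_series(seg, band_list, config.tol_window_s))
            log_event("bands", file=f["path"], windows=len(tol_parts[-1].window_start_times))

        if "detect" in config.stages or "seismic" in config.stages:
            lf_seg = tn.decimate_lf(seg)
            lf_spec = tn.spectrogram(lf_seg, tn.LF_FFT, tn.LF_HOP)
            if "detect" in config.stages:
                lf_excess = tn.excess_map(lf_spec)
                lf_binary = ((lf_excess > config.tonal_threshold_db)
                             & ((lf_spec.bin_frequencies < tn.SPLIT_HZ)
                                & (lf_spec.bin_frequencies >= tn.MIN_FREQ_HZ))[None, :])
                moans = tn.extract_contours(lf_binary, lf_spec, "LF_moan",
                                            excess_db=lf_excess)
                whistles = (tn.detect_tonals(seg, "HF", config.tonal_threshold_db)
                            if seg.sample_rate > tn.LF_RATE else [])
                tonal_records += tn.contours_to_records(moans + whistles)
                clicks = tr.click_detect(seg, config.click_threshold_db)
                click_detections += clicks
                transient_records += tr.detections_to_records(clicks)
                log_event("detect", file=f["path"], moans=len(moans),
                          whistles=len(whistles), clicks=len(clicks))
            pulses = tr.energy_sum_detect(lf_spec, config.energy_sum_threshold_db)
            energy_detections += pulses
            transient_records += tr.detections_to_records(pulses)
            log_event("energy_sum", file=f["path"], detections=len(pulses))

    if not recording_intervals:
        config.to_yaml(outdir / "effective_config.yaml")
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
        raise RuntimeError("no input files could be processed")

    products = []
    tols = bd.TOLSeries.concat(tol_parts) if tol_parts else None

    if "bands" in config.stages and tols is not None:
        tols.to_long().to_csv(outdir / "tol_long.csv", index=False)
        decades = bd.decade_series(tols)
        decades.to_csv(outdir / "decade_levels.csv", index_label="time")
        exc = pd.DataFrame({b.nominal_centre: bd.exceedance(
            tols.levels[:, j], config.exceedance_percentages)
            for j, b in enumerate(tols.bands)
            if np.isfinite(tols.levels[:, j]).any()})
        exc.to_csv(outdir / "exceedance.csv", index_label="p")
        products += ["tol_long.csv", "decade_levels.csv", "exceedance.csv"]

    if "qc" in config.stages and tols is not None:
        diags = qcmod.band_diagnostics(tols)
        qcmod.diagnostics_frame(diags).to_csv(outdir / "band_diagnostics.csv",
                                              index=False)
        products.append("band_diagnostics.csv")

    if "detect" in config.stages:
        with open(outdir / "tonal_detections.jsonl", "w") as fh:
            for rec in tonal_records:
                fh.write(json.dumps(rec) + "\n")
        with open(outdir / "transient_detections.jsonl", "w") as fh:
            for rec in transient_records:
                fh.write(json.dumps(rec) + "\n")
        products += ["tonal_detections.jsonl", "transient_detections.jsonl"]

    if "seismic" in config.stages:
        table = sc.classify_deployment(
            energy_detections,
            window_length_s=config.seismic_window_s,
            start=recording_intervals[0][0] if recording_intervals else None,
            end=recording_intervals[-1][1] if recording_intervals else None,
            targets=config.seismic_targets_s,
            tol=config.seismic_tol_s,
            min_run=config.seismic_min_run,
            run_window=config.seismic_run_window_s,
        )
        table.to_csv(outdir / "seismic_windows.csv", index=False)
        products.append("seismic_windows.csv")

    if "summarize" in config.stages and recording_intervals:
        start = recording_intervals[0][0]
        end = recording_intervals[-1][1]
        count_tables = {}
        for label, dets in (("click", click_detections),
                            ("energy_sum", energy_detections)):
            count_tables[label] = sm.bin_counts(
                [d.time for d in dets], config.count_bin, start, end,
                recording_intervals)
        counts = pd.DataFrame(count_tables)
        sm.yearly_truncate(counts).to_csv(outdir / "detections_10min.csv",
                                          index_label="bin_start")
        products.append("detections_10min.csv")
        if tols is not None:
            decades = bd.decade_series(tols)
            sm.weekly_median(decades).to_csv(outdir / "weekly_median_decades.csv")
            sm.monthly_exceedance(tols.to_frame()).to_csv(
                outdir / "monthly_exceedance.csv")
            products += ["weekly_median_decades.csv", "monthly_exceedance.csv"]

    config.to_yaml(outdir / "effective_config.yaml")
    log_event("done", products=products)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    if not products:
        raise RuntimeError("pipeline produced no products")
    return outdir
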