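"""Calendar products and period summaries.

Bins the detector outputs into 10-min calendar counts (absent, not zero,
during duty-cycle gaps), summarises decade levels as weekly medians and
monthly exceedance tables, and renders an optional polar (one-year)
calendar figure of the transient counts.

Writes results/detections_10min.csv, results/weekly_median_decades.csv,
results/monthly_exceedance.csv and results/calendar_transients.png.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from hydroscape import bands as bd  # noqa: E402
from hydroscape import calibration as cal  # noqa: E402
from hydroscape import summaries as sm  # noqa: E402
from hydroscape.pipeline import _load_manifest  # noqa: E402

SCENE_DIR = REPO / "scratch" / "analysis_scene"
RESULTS = REPO / "results"


if __name__ == "__main__":
    records = [json.loads(line) for line in
               (RESULTS / "transient_detections.jsonl").read_text().splitlines()]
    times = [pd.Timestamp(r["time"]) for r in records]
    meta, files = _load_manifest(SCENE_DIR / "SYN01_manifest.yaml")
    raw, _ = cal.read_wav(files[0]["path"])
    seg = cal.calibrate(raw, meta, pd.Timestamp(files[0]["start_time"]))

    counts = sm.bin_counts(times, "10min", start=seg.start_time,
                           end=seg.end_time,
                           recording_intervals=[(seg.start_time, seg.end_time)])
    counts.to_frame("transients").to_csv(RESULTS / "detections_10min.csv")
    print("10-min transient counts:", counts.to_dict())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tols = bd.tol_series(seg, bd.nominal_bands(10, 12500))
    decades = bd.decade_series(tols)
    sm.weekly_median(decades).to_csv(RESULTS / "weekly_median_decades.csv")
    sm.monthly_exceedance(tols.to_frame()).to_csv(
        RESULTS / "monthly_exceedance.csv")
    print("weekly median decade levels:")
    print(sm.weekly_median(decades).round(1).to_string())

    sm.plot_calendar(counts, RESULTS / "calendar_transients.png",
                     title="Transient detections per 10 min")
    print(f"calendar figure -> {RESULTS / 'calendar_transients.png'}")
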