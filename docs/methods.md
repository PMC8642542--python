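# Methods

`hydroscape` implements a long-term passive-acoustic-monitoring (PAM)
analysis chain for single-channel autonomous hydrophone recordings:
calibrated third-octave and decade band levels with exceedance statistics,
flow-noise and recorder self-noise quality control, generic tonal and
transient detectors, an inter-pulse-interval (IPI) classifier for seismic
airgun activity, and a synthetic scene generator that provides ground
truth where archived sea recordings are unavailable.

## Calibration model

Recorders store 16-bit counts; digital full scale (±32768) maps to the
system *peak* clipping level `C` in dB re 1 µPa, so

    p[µPa] = raw / 32768 · 10^(C/20),      default C = 151 dB re 1 µPa.

The mapping is linear and exactly invertible for unclipped samples; the
clipped fraction (|raw| ≥ 32767) is tracked per segment. The hydrophone
frequency response is treated as flat (no equalisation). Absolute time
comes from a sidecar manifest, never from WAV headers; duty-cycle gaps are
represented as absent segments and never zero-filled, so scheduled silence
cannot bias RMS statistics. The first and last 24 h of a deployment are
trimmed (deployment-vessel noise); deployments shorter than 48 h trim to
nothing, with a warning.

## Band levels

Third-octave bands use base-2 ANSI centres `1000·2^(n/3)` Hz with edges
`centre·2^(∓1/6)`; nominal centres follow preferred-number rounding
(10, 12.5, 16, … Hz). Each band is measured with a band-pass Butterworth
filter with **6 poles total** (3rd-order low-pass prototype), implemented
as second-order sections for stability at 10 Hz against a 32768 Hz rate.
Filters run **once per contiguous segment** with persistent state; 10-s
non-overlapping windows slice the filtered output, so no per-window
start-up transients occur. The first window of each segment, which does
contain the filter's start-up, is flagged rather than dropped. Bands whose
upper edge exceeds 0.95× Nyquist are omitted with a warning (this
reproduces the 3.15/6.3/12.5 kHz top bands at the three standard rates).
Silent windows yield NaN, never −∞ or 0.

Decade levels (VLF 10–100, LF 100–1000, MF 1000–10000 Hz) sum third-octave
intensities, weighting each band by its linear-frequency overlap fraction
with the decade. Exceedance levels L_p (level exceeded by p% of windows)
are the (100−p)-th percentile with linear interpolation between order
statistics. For comparison with the 63 Hz / 125 Hz / 2 kHz indicator
bands, the bandwidth compensation `round(10·log10(BW_dec/BW_band))`
evaluates to 8, 15 and 13 dB.

Two numerical facts worth knowing: the 6-pole skirts pass an adjacent-band
tone at about −18 dB, so a pure tone's decade level exceeds its band level
by ~0.13 dB, and a >10 dB level cliff between adjacent decades leaks
visibly (~1 dB) across the boundary. Real sloped ambient spectra do not
contain such cliffs; synthetic scenes therefore keep adjacent-decade steps
within ~10 dB.

## Flow-noise and self-noise QC

Flow pseudo-noise over a moored hydrophone is tidally modulated. Per band,
10-s levels are medianed per clock hour; the hourly series (gaps filled
with the series median, mean removed, FFT size = series length) yields a
magnitude periodogram whose bin k corresponds to a period of N/k hours. A
band is flagged tidal when a local maximum inside the [5.5, 6.8] h or
[11.5, 13.0] h windows exceeds the loudest bin *outside* those windows by
≥ 6 dB. The reference point matters: raw single-bin FFT magnitudes are
Rayleigh-distributed with ~5.6 dB spread, so the extreme of the ~30
in-window bins sits 8–11 dB above the *median* even for white input; a
genuine tidal line instead dominates the entire spectrum (a ±3 dB
modulation over 30 days stands ~20 dB above the noise bins), which the
off-window-maximum reference exploits. At least 48 hourly values are
required.

Self-noise limitation is assessed per band on ≥ 100 level values, by two
rules in fixed order: (1) |L_90 − L_99| < 0.5 dB → flagged, estimate
L_99; (2) Gaussian kernel density (Silverman bandwidth) at the minimum
observed level exceeding 0.05 of the maximum density → flagged, estimate =
minimum level. Rule 2 operationalises the "lowermost violin width" of a
violin plot as the density value at the distribution's minimum. Flagged
bands are annotated only — no level correction is applied, and flagged
bands stay in the reported statistics. A cubic polynomial in log10(f)
through ≥ 4 flagged-band estimates summarises the floor for illustration.

## Tonal detection (whistles and moans)

Two spectrogram paths split at 1500 Hz: the HF path (whistles) runs at the
native rate with FFT 1024 / hop 512 / Hann; the LF path (moans) first
low-pass filters (4-pole Butterworth, 1500 Hz) and polyphase-resamples to
3000 Hz, then uses FFT 512 / hop 256 / Hann. Bin widths are 3000/512 =
5.86 Hz (LF) and 32 Hz at 32768 Hz (HF). The 4-pole anti-alias filter
passes 500 Hz within 0.1 dB and attenuates 2500 Hz by > 20 dB after
resampling; its response at 1200 Hz is 0.67 dB down (the 0.5 dB point of a
4-pole filter with 1500 Hz cut-off sits near 1130 Hz).

Per bin, a decaying background B ← (1−α)·B + α·mag with α = 0.02 (seeded
with the median of the first 10 frames) estimates the noise floor; frames
are compared against the pre-update background. The background-subtracted
excess is then smoothed along time with a short moving average (3 frames
LF, 5 frames HF ≈ half the minimum event duration) before thresholding at
8 dB. This smoothing is the noise-reduction step: the dB excess of
Gaussian noise has a ~5.6 dB per-pixel spread, and an unsmoothed 8 dB
threshold (≈ 3% pixel rate) chains into tens of false contours per minute;
averaging along time leaves any signal that persists across frames — the
defining property of a tonal — intact while shrinking the noise spread by
~√k. Bins below 10 Hz (the analysis floor; DC-adjacent bins carry only
filter roll-off) are masked.

Connected components link pixels in adjacent frames whose bins differ by
≤ 2 (via frequency dilation + 8-connected labelling). A component becomes
a contour if it lasts ≥ 150 ms (HF) / 300 ms (LF), spans ≥ 2 distinct
bins, and holds on average ≥ 2 pixels per frame — a genuine tonal always
paints its analysis-window mainlobe (2 bins), whereas residual chance
chains in smoothed noise are single-pixel threads. Per frame the contour
frequency is the magnitude-weighted centroid of the component's bins.
Overlapping whistles may merge; no crossing disambiguation is attempted.

Consequences of the adaptive background worth knowing: a tonal lasting
longer than ≈ 1/α frames (~4 s at LF defaults) is progressively absorbed
into the background and its tail truncated; and the reverberant tails of
airgun pulses (several hundred ms of band-limited decay) legitimately
trigger the LF moan path, as the field detectors do on real seismic
recordings.

## Transient detection

**Click detector.** The signal is high-passed (4-pole Butterworth,
3000 Hz) and squared; a fast exponential moving average (α_s = 0.1) tracks
the signal and a slow one tracks the noise, with the smoothing-length
difference four orders of magnitude below threshold (α_n = 10⁻⁵) and five
above (10⁻⁶), so the noise estimate effectively freezes during an event. A
detection opens when 10·log10(fast/slow) > 12 dB and closes when it falls
below; events separated by < 2 ms merge; events outside 0.1–50 ms are
discarded (longer impulses belong to the energy-sum path). The
sample-by-sample tracker is JIT-compiled (numba); the pure-Python fallback
is behaviourally identical.

**Energy-sum detector.** On the LF spectrogram (the same 3000 Hz / FFT
512 / hop 256 chain as the moan detector), per-frame energy E = Σ |X|²
over the 0–600 Hz bins is compared against a slow exponential background
(α = 0.005, slowed ×10 while a detection is open, mirroring the click
detector's freeze). Detection while 10·log10(E/background) > 8 dB; events
split by ≤ 2 below-threshold frames merge (reverberation dropouts).
Detection timestamps are the energy-weighted centroid of the event's
frames: sub-hop timing matters because frame-start timestamps quantise
pulse-train gaps to the 85 ms hop, which can split the IPI histogram's
modal count between adjacent bins.

## Seismic airgun classification

Within each analysis window (default 30 min; the field analysis used
individual files of 26–135 min) all pairwise intervals ≤ 30 s between
energy-sum detections are computed; the 30 s cap bounds harmonics of the
largest target IPI. The modal IPI is the centre (multiple of 0.1 s) of the
sliding **400 ms counting window** capturing the most intervals — the same
tolerance window used for target matching — with ties broken toward the
centre nearest the captured intervals' median, then toward the smaller
interval. A sliding window rather than disjoint 0.1-s bins is essential:
detection-time jitter of a few tens of ms splits the true-IPI count
between adjacent narrow bins while the double-interval harmonic (whose
jitter is the sum of two, similarly spread) stays concentrated, letting
the harmonic win.

Activity is present when (a) the mode lies within ±0.2 s of a target IPI
(12, 14 or 18.5 s) and (b) at least 15 consecutive pulses chain within
600 s. Chaining tolerates gaps of target ± 0.4 s (2× the mode tolerance,
because the jitter of a *gap* combines the timing error of both pulses),
bridges a single missed pulse (gap ≈ 2×target ± 0.4 s), and skips clutter
detections falling inside a pulse slot rather than breaking the chain.
All targets, tolerances and run parameters are configurable; defaults are
the published ones. A successive-difference IPI variant is available by
configuration.

## Summaries

Detections are binned into half-open 10-min (or daily) calendar bins;
boundary events count in the later bin; bins inside duty-cycle gaps are
absent (NaN), not zero. Weekly medians use ISO weeks and pool same-week
data across years per station (a per-year variant exists); monthly tables
use calendar months. Series longer than one year truncate to the first
365 days for circular presentation. Distribution summaries (violin/box)
return a Gaussian KDE plus quartiles and the L_1…L_99 set; rendering
(polar calendar PNGs) is a thin optional layer over the numeric products
and is untested by design — correctness lives in the numbers.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes,
not ocean physics (no propagation, source levels or sound-channel
effects):

- **Ambient noise** is Gaussian, shaped in the frequency domain to a
  power-law slope (default −14 dB/decade, a typical deep-water shape) and
  rescaled per decade so the realised RMS band level meets its target
  exactly; out-of-range bins follow the nearest decade's scaling. Default
  targets VLF 100 / LF 95 / MF 85 dB re 1 µPa sit inside the quiet-region
  envelope of published Arctic observations (LF medians spanning roughly
  84–114 dB re 1 µPa).
- **Tidal flow-noise** is a multiplicative slow gain (default period
  12.42 h — the semidiurnal M2 constituent — and a dB-sinusoidal depth)
  applied only to the component below a 200 Hz ceiling, mirroring the
  observation that the signature fades above the 100–200 Hz bands.
- **Self-noise floors** are additive stationary brick-wall band noise at
  stated third-octave levels with exact in-band RMS, so a third-octave
  measurement recovers the stated floor.
- **Events**: airgun trains (noise bursts under an exp(−t/τ) envelope,
  band-passed one octave around 150 Hz with a steep 4th-order filter so
  out-of-band skirts stay below ambient; exact jittered pulse times are
  logged), log-frequency down-sweeps with Hann envelopes (bearded-seal-
  like; midpoint frequency = geometric mean), vibrato moans, broadband
  clicks and pure tones. Event SNR is defined as the event's RMS band
  level minus the ambient band level in the event's occupied band over
  the event duration — matching how the detectors' relative thresholds
  operate. The Hann envelope means a sweep's extreme frequencies carry no
  energy, so recovered contours cover the audible middle of the sweep,
  not its nominal endpoints.
- The rendered waveform passes through the 16-bit calibration inverse, so
  analysis code sees exactly what reading the written WAV would give;
  clipping is applied and logged. Identical (spec, seed) pairs are
  byte-identical.
- **Long-duration QC scenarios** (30-day periodograms) are generated
  directly as hourly level series; a month of audio would add nothing but
  compute, since the periodogram consumes only hourly medians.

What a green synthetic test does *not* establish: performance on real
Arctic soundscapes with ice noise, shipping, overlapping biological
choruses, mooring strum or propagation effects; detector thresholds here
stand in for unpublished field-software defaults and are exposed in
configuration rather than validated against the original detectors.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation between closest ranks.
- All-zero windows → NaN levels; empty exceedance input → error;
  < 100 values → self-noise indeterminate; < 48 h → periodogram error;
  < 4 flagged bands → no cubic fit.
- KDE bandwidths: Silverman (self-noise rule), Scott (violin summaries);
  constant distributions short-circuit before KDE (rule 1 already fires).
- Seeds: a scene seed spawns independent child streams (ambient, self-
  noise, each event), so adding an event never perturbs the others.
- Timestamps are UTC throughout; windows are half-open [t, t+Δ); sample
  indices 0-based.

## Known limitations

- The LF moan path fires on airgun reverberation tails (physically
  expected, but it inflates "moan" counts during seismic activity).
- The background tracker absorbs tonals longer than ~4 s.
- Flow-noise is flagged, never corrected; flagged self-noise bands are
  annotated, not excluded, so medians in censored bands remain
  overestimates.
- Overlapping tonal contours merge; no species classification is
  attempted.
- WAV input is limited to mono 16-bit RIFF PCM.
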