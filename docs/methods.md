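# Methods

## The Sv DC field and why it is analysed this way

Intracranial EEG contains a slow, aperiodic component below 0.5 Hz that most
clinical pipelines remove. This package treats that component — the
slow-varying DC (Sv DC) field — as the primary observable. Two equivalent
definitions are implemented: the output of a zero-phase second-order
Butterworth low-pass with 0.5 Hz cutoff (`extract_svdc`), and the per-2-second
piecewise mean (`piecewise_dc`). On signals whose power is concentrated below
0.5 Hz the two agree to correlation ≥ 0.9 (tested); the filter definition is
used everywhere downstream because it yields a smooth series.

The analysis rests on three empirical regularities that the package makes
quantitative:

1. **Energy dominance.** Over the 4-minute peri-ictal window (2 min before to
   2 min after onset — chosen because seizures typically last 1–2 min) the
   Sv DC band holds the majority of signal energy on most leads. The statistic
   is the per-lead ratio of the band's time-domain sum of squares to the full
   preprocessed (0.01–300 Hz) signal's sum of squares, summarised as the
   fraction of leads at or above 60% and 90% (inclusive thresholds).
2. **Dispersion precedes fast activity.** After referencing each lead's Sv DC
   to its pre-ictal mean, the cross-lead standard deviation per 2-s window
   ("dispersion") rises before LF (0.5–40 Hz) or HF (40–300 Hz) energy does.
   Dispersion is invariant to any signal shared by all leads, so it isolates
   *local* voltage divergence from global shifts.
3. **Interictal fluctuation marks the epileptogenic zone.** Between seizures,
   leads outside the epileptogenic zone track a common slow trend; leads
   inside it fluctuate around that trend. Leads are ranked by the SD of their
   residual against the cross-lead *median* trend (median, so a single extreme
   lead cannot drag the trend it is scored against).

## Filters

All filters are applied forward–backward (zero-phase). Rationale: the central
claims are about *timing* (which component moves first), and causal filtering
would delay each band by a different group delay. Consequences, documented
and tested: the effective order doubles, and gain at a cutoff frequency is
1/2 rather than 1/√2.

Zero-phase filtering of *large slow transients* has its own pathology: the
0.01 Hz high-pass edge of the preprocessing band-pass smears a several-hundred
µV ictal DC plateau tens of seconds backward in time (its slowest pole decays
with τ ≈ 40 s), which would bias dispersion onsets early and reconvergence
late. The timing analyses (dispersion, reconvergence, lead ranking) therefore
apply the Sv DC low-pass to the *notch-filtered* signal, skipping the 0.01 Hz
high-pass; energy ratios keep the full preprocessed signal as their
denominator, as the ratio definition requires. Reflect padding of one filter
settling length (1/f_low seconds, capped at the record length) is used so
start-up transients stay outside the record; energy traces additionally
exclude a 12-s guard at the record edges, where the residual transient is
measurable.

A related caveat governs verification: the designed stopband residual of the
0.01–300 Hz band-pass at 400 Hz is ~0.2% in amplitude, below the slow edge
transient on records shorter than a few minutes. The filter-contract test
therefore measures tone attenuation by projection onto the quadrature pair at
the tone frequency, which is orthogonal to the slow transient.

## Detection rules and their defaults

| Rule | Default | Why |
| --- | --- | --- |
| Notch | 50 Hz, Q = 30 | mains frequency; Q chosen for a ~1.7 Hz stopband |
| Broadband | 0.01–300 Hz, order 4 | retains the analysis range |
| Artifact drift | baseline outside ±100 µV for ≥ 10 s | moving-median baseline over 10 s; the voltage bound is the standard screening rule, the duration operationalises "continuous" |
| Discontinuity | ≥ 500 µV per sample | electrode-contact artifacts; configurable |
| Dispersion onset | median + 3·MAD, sustained ≥ 10 s | ictal values are extreme outliers, so robust baseline statistics; the sustained-run rule suppresses isolated noise windows |
| Active phase | 6-s windows, energy ≥ 2× the preceding-hour mean, runs ≥ 12 s, gaps < 6 s merged | the 100%-increase criterion with a 6-s window; run/merge durations are two windows/one window |
| Baseline | mean 6-s window energy over the hour before the observation span, clipped to available history with a note | |
| Stages | seizure span split into equal thirds | matches the three-panel staging convention; explicit boundaries accepted |
| PLV band | HF (40–300 Hz) by default | ictal synchronization analysis pairs naturally with fast activity; the band is configurable because no canonical choice exists |

Artifact flagging in the ictal pipeline is evaluated on the pre-onset
background (up to 60 s before onset): a genuine ictal DC shift of several
hundred µV would otherwise trip the drift rule that exists to catch electrode
artifacts. Flagged channels are retained in files but excluded from all
statistics, with both counts reported.

Onsets are reported at the start of the first qualifying window, so detection
granularity equals the window length (2 s). `svdc_first` is true only when
the dispersion onset exists and strictly precedes every detected band onset.

## The synthetic generator

No recordings with known ground truth exist for these phenomena, so the
package ships a seeded phenomenological generator (`svdc.simulate`) whose
defaults define the study conditions used by every recovery test:

* **Background**: per-lead 1/f noise (15 µV RMS, exponent 1) whose spectrum
  flattens below 0.5 Hz, plus a weak common 10 Hz oscillation (3 µV), a
  shared slow trend (10 µV, 0.01–0.4 Hz) and a per-lead slow residual
  (4 µV, 0.05–0.45 Hz). Flattening the lead-specific noise below 0.5 Hz is
  deliberate: independent unbounded 1/f wander would make the cross-lead
  dispersion baseline nonstationary, which is a property of electrode drift,
  not of the shared physiology the trend models. The residual band starts at
  0.05 Hz so it stays stationary over a few-hundred-second analysis span.
* **Seizure**: per-lead signed Sv DC offsets (scale 400 µV, drawn uniformly
  in [0.6, 1.6]× that scale, ×1.5 on SOZ leads; signed so the field
  *disperses* rather than shifts), raised-cosine rise over 10 s starting
  20 s (`dc_lead_time_s`) before each lead's event time, plateau to seizure
  end, raised-cosine fall over 20 s. The fall is raised-cosine rather than
  exponential so the ground-truth reconvergence time (end + fall) is well
  defined. Fast activity: 3 Hz rhythm at 80 µV and an 80–250 Hz LVFA burst
  at 20 µV from each lead's event time. The DC amplitudes are
  order-of-magnitude choices — macro-contact ictal DC shifts are reported
  from tens of µV to mV — and are exposed in the config. The smooth DC
  waveform is verified to leave HF-band energy unchanged (±5%) in the
  lead-in window, so onset-ordering recovery cannot be a leakage artifact.
* **Propagation**: `pathway` mode recruits leads at 2-s intervals in spatial
  order (contact index, then electrode letter); `volume` mode starts all
  leads together and mixes a single common waveform (250 µV LF + 30% HF
  content) into every lead with gain ramping linearly over the seizure, so
  staged cross-lead correlation rises toward 1 — the volume-conduction
  signature.
* **Interictal**: broadband background energy ×4 (amplitude ×2) inside
  designated active intervals, so the 100% energy rule fires with margin;
  SOZ leads' slow residual ×5 (`soz_fluctuation_gain`).

What the generator does **not** emulate: biophysical ion dynamics, realistic
seizure waveform morphology (spike-wave complexes, chirps), nonstationary
background (sleep stages, medication effects), shared-reference or montage
artifacts, and spatially graded lead-to-lead correlation. Passing recovery
tests therefore demonstrate that the *algorithms* recover the stated
structure under realistic amplitudes and noise — not that the thresholds are
clinically validated on patient data.

## Problem sizes in the test suite

Recovery studies run at the generator's native 1024 Hz with 8 leads:
480-s records for ictal studies (20 seeds for latency recovery, 10 for the
volume-conduction signature), 600-s records for lead ranking (50 seeds), and
1200-s records for active-phase recovery (20 seeds; the preceding-hour
baseline clips to the 600 s of available history, exercising the documented
clip rule). These sizes keep each study's sampling error far below the
margins being asserted.

## Numerical conventions and degenerate inputs

* Time: seconds from record start; half-open windows [t0, t1); sample i
  covers [i/fs, (i+1)/fs).
* Energies are plain float64 sums of squares (µV²·samples); additivity over
  disjoint windows holds to machine precision and is property-tested.
* Zero-energy leads yield missing (NaN) ratios, never 0, and are excluded
  from threshold fractions with separate bookkeeping.
* Constant signals make the cross-correlation denominator zero: NaN with a
  warning. The autocorrelation normalises by full-signal energy as defined,
  so ρ(0) = 1 exactly and |ρ(τ)| shrinks by (1 − |τ|/T) for white-ish
  signals — this is the definition's behaviour, not a bug.
* A zero-MAD dispersion baseline falls back to a configurable absolute
  floor, with a warning.
* EDF writing requires an integer sampling rate and pads the final 1-s
  record with zeros (warning) when the record is not a whole number of
  seconds; physical scaling uses 16-bit quantization of the per-channel
  range. Mixed per-signal rates and duplicate labels are rejected on read.

## Known limitations

* The dispersion onset rule has 2-s granularity and assumes a quiet
  reference interval (default: 120 s ending 30 s before the analysis
  window); a seizure that begins during the reference interval will inflate
  the baseline and delay detection.
* The lead ranking is meaningful only when fluctuation contrasts exceed
  sampling error; with exchangeable leads the scores tie within ~20% and the
  ranking is arbitrary (documented behaviour, tested).
* Hour-scale windows are clipped to the available record with a note; the
  package does not resample, re-reference, or interpolate bad channels.
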