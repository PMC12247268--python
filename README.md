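# svdc — slow-varying DC field analysis of intracranial EEG

Clinical EEG pipelines routinely high-pass away everything below ~0.5 Hz.
In stereo-EEG (SEEG) recordings of focal epilepsy, that discarded band — the
**slow-varying DC (Sv DC) field**, the 0.01–0.5 Hz component, equivalently the
2-second piecewise mean of the signal — turns out to carry most of the ictal
signal energy, and its *cross-lead dispersion* begins before the low-voltage
fast activity (LVFA) and rhythmic activity that conventionally mark
electrographic seizure onset. `svdc` implements this analysis as a reusable,
tested Python library for electrophysiologists and methods researchers:

* **Preprocessing** — 50 Hz notch, 0.01–300 Hz 4th-order Butterworth
  band-pass, numeric artifact-channel flagging (±100 µV sustained drift,
  sample-to-sample discontinuities, clipping). All filters zero-phase.
* **Band decomposition** — Sv DC (2nd-order Butterworth low-pass, 0.5 Hz
  cutoff), LF (0.5–40 Hz) and HF (40–300 Hz) bands; the 2-s piecewise-mean
  DC as an alternative definition.
* **Energy metrics** — the Sv DC energy ratio
  `r = Σ x_svdc²(t) / Σ x²(t)` over the 4-minute peri-ictal window
  (2 min before to 2 min after onset) and an hour-scale window; lead-count
  summaries at the ≥ 60% / ≥ 90% thresholds; 6-s sliding-window energy;
  interictal *active phases* (energy ≥ 2× the preceding-hour baseline) with a
  Wilcoxon rank-sum stable-vs-active comparison.
* **Dispersion** — cross-lead SD of baseline-referenced Sv DC per 2-s window;
  robust onset detection (median + 3·MAD, sustained ≥ 10 s); onset ordering
  against LF/HF band onsets; post-ictal reconvergence; interictal lead
  ranking by Sv DC fluctuation around the shared cross-lead trend
  (epileptogenic-zone candidate marker).
* **Propagation networks** — autocorrelation
  `ρ(τ) = ∫ s(t)s(t+τ)dt / ∫ s²(t)dt`, mean-centred cross-correlation
  `ρ₁₂`, and the phase-locking value
  `PLV = (1/N) |Σₙ exp(j θ(n))|` on Hilbert phases, evaluated per seizure
  stage (equal thirds) to separate pathway propagation from volume-conduction
  spread (correlation → 1 late in the seizure).
* **Synthetic SEEG generator** — seeded, annotated multi-lead recordings with
  ground truth (per-lead DC/LF/HF onset latencies, SOZ leads, active
  intervals), used to validate every stage by parameter recovery, because no
  public dataset carries these phenomena with known truth.

## Worked example

```python
import svdc

cfg = svdc.SimConfig(seed=42)            # 8 leads, 1024 Hz, seizure at 240 s,
rec, truth = svdc.generate_ictal(cfg)    # Sv DC lead time 20 s
report = svdc.run_ictal_analysis(rec, truth.seizure_onset_s)
s = report.scalars
print(s["dispersion_onset_s"], s["lf_onset_s"], s["latency_svdc_to_lf_s"])
```

prints

```
220.0 240.0 20.0
```

— the detected Sv DC dispersion onset (220 s) precedes the LF/HF activity
onset (240 s) by exactly the injected 20-s lead time. On the same recording
the per-lead Sv DC energy ratios over the 4-min ictal window
(`report.tables["energy_ictal"]`) lie between 0.52 and 0.86, with 7 of 8
leads ≥ 0.6: the slow field dominates the seizure's energy budget. The
scripts in `examples/` walk through each capability (simulation, energy
ratios, dispersion onset, interictal phases and lead ranking, staged
propagation networks) and print a line explaining each number.

A thin CLI mirrors the library (`svdc simulate`, `preprocess`, `bands`,
`energy`, `phases`, `dispersion`, `rank-leads`, `network`, `run-ictal`,
`run-interictal`); recordings are read/written as EDF/EDF+ or delimited text.

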