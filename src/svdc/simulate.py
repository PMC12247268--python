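"""Seeded synthetic SEEG generator with ground truth.

Emulates the statistical structure the analysis stages assume, in place of
clinical recordings that are not publicly deposited:

* multi-lead background: per-lead pink (1/f) noise plus a weak common
  oscillation and a shared slow (< 0.5 Hz) trend;
* seizures: a per-lead slow DC offset (raised-cosine rise to a plateau,
  raised-cosine fall back to baseline after seizure end) whose signed
  amplitudes differ across leads — the field *disperses* rather than shifts —
  starting ``dc_lead_time_s`` before the fast activity; rhythmic LF activity
  and a low-voltage fast-activity (LVFA) burst starting at each lead's event
  time;
* two propagation modes: ``pathway`` (LVFA recruits leads one by one with a
  fixed inter-lead delay) and ``volume`` (all leads start together and a
  common waveform is mixed into every lead with a gain ramping up through the
  seizure, so late-stage cross-lead correlations approach 1);
* interictal recordings with designated active intervals (background energy
  multiplied by ``active_gain``) and epileptogenic-zone (SOZ) leads whose
  residual Sv DC fluctuation around the shared trend is amplified by
  ``soz_fluctuation_gain``.

Everything is deterministic given (seed, config). The generator is
phenomenological: no biophysical ion-dynamics model is simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .io import Annotation, Recording, parse_lead_label, write_recording

__all__ = [
    "NoiseConfig",
    "SeizureConfig",
    "InterictalConfig",
    "SimConfig",
    "SynthGroundTruth",
    "make_labels",
    "generate_background",
    "inject_seizure",
    "generate_ictal",
    "generate_interictal",
    "generate_study",
]


@dataclass
class NoiseConfig:
    """Background composition (amplitudes in uV)."""

    pink_exponent: float = 1.0
    pink_floor_hz: float = 0.5  # spectrum flattens below this; slow structure
    # is carried by the shared trend + per-lead residual instead, so the
    # lead-specific slow wander stays stationary
    rms_uv: float = 15.0
    common_osc_uv: float = 3.0
    common_osc_hz: float = 10.0
    trend_uv: float = 10.0  # shared slow (<0.4 Hz) trend
    resid_svdc_uv: float = 4.0  # per-lead slow residual around the trend


@dataclass
class SeizureConfig:
    """Ictal event parameters; amplitudes in uV, times in s."""

    onset_s: float = 240.0
    duration_s: float = 90.0  # seizures typically last 1-2 min
    dc_lead_time_s: float = 20.0
    dc_shift_uv: float = 400.0  # per-lead magnitudes drawn around this scale
    dc_rise_s: float = 10.0
    dc_fall_s: float = 20.0
    propagation: str = "pathway"  # or "volume"
    inter_lead_delay_s: float = 2.0
    lvfa_amp_uv: float = 20.0  # "low-voltage" fast activity
    lvfa_band: tuple[float, float] = (80.0, 250.0)
    lf_rhythm_hz: float = 3.0
    lf_amp_uv: float = 80.0
    common_mix_uv: float = 250.0  # volume mode: common waveform amplitude


@dataclass
class InterictalConfig:
    active_intervals: list = field(default_factory=list)  # [(t0, t1), ...]
    active_gain: float = 4.0  # energy gain (amplitude x2) in active intervals
    soz_fluctuation_gain: float = 5.0


@dataclass
class SimConfig:
    """Full study-condition description for one synthetic recording."""

    n_electrodes: int = 2
    contacts_per_electrode: int = 4
    fs: float = 1024.0
    duration_s: float = 480.0
    seed: int = 0
    soz_leads: tuple[str, ...] = ("A1", "A2")
    seizure: SeizureConfig = field(default_factory=SeizureConfig)
    interictal: InterictalConfig = field(default_factory=InterictalConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def labels(self) -> list[str]:
        return make_labels(self.n_electrodes, self.contacts_per_electrode)

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be positive")
        labels = set(self.labels())
        missing = set(self.soz_leads) - labels
        if missing:
            raise ParameterError(f"soz leads {sorted(missing)} not generated")
        # seizure timing is validated against the actual recording in
        # inject_seizure, so interictal configs may carry a default section


@dataclass
class SynthGroundTruth:
    """Generator-side truth for parameter-recovery tests."""

    seizure_onset_s: float | None = None
    dc_onsets: dict = field(default_factory=dict)  # label -> s
    lf_onsets: dict = field(default_factory=dict)
    hf_onsets: dict = field(default_factory=dict)
    soz_leads: tuple[str, ...] = ()
    active_intervals: list = field(default_factory=list)
    reconvergence_s: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def make_labels(n_electrodes: int, contacts: int) -> list[str]:
    if not (1 <= n_electrodes <= 26) or contacts < 1:
        raise ParameterError("need 1-26 electrodes and >= 1 contact each")
    return [
        f"{chr(ord('A') + e)}{c}"
        for e in range(n_electrodes)
        for c in range(1, contacts + 1)
    ]


def _spatial_order(labels: list[str]) -> list[int]:
    """Pathway recruitment order: contact index first, then electrode letter."""
    parsed = [parse_lead_label(l) for l in labels]
    return sorted(range(len(labels)), key=lambda i: (parsed[i].contact, parsed[i].electrode))


def _band_noise(rng, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [low, high] Hz via FFT masking."""
    spec = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    freqs = np.fft.fftfreq(n, d=1 / fs)
    mask = (np.abs(freqs) >= low) & (np.abs(freqs) <= high)
    spec[~mask] = 0
    x = np.real(np.fft.ifft(spec))
    rms = np.sqrt(np.mean(np.square(x)))
    return x / rms if rms > 0 else x


def _pink_noise(rng, n: int, fs: float, alpha: float, floor_hz: float = 0.0) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise (power spectrum), DC removed.

    Below ``floor_hz`` the spectrum is held flat at its value at the floor,
    keeping the ultra-slow wander of independent channels bounded.
    """
    spec = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    freqs = np.fft.fftfreq(n, d=1 / fs)
    f_eff = np.maximum(np.abs(freqs), max(floor_hz, fs / n))
    shaping = f_eff ** (-alpha / 2)
    shaping[freqs == 0] = 0.0
    x = np.real(np.fft.ifft(spec * shaping))
    rms = np.sqrt(np.mean(np.square(x)))
    return x / rms if rms > 0 else x


@dataclass
class _Components:
    """Background split into parts so callers can re-weight them."""

    broadband: np.ndarray  # per-lead pink noise + common oscillation
    trend: np.ndarray  # shared slow trend, one row broadcast to all leads
    resid: np.ndarray  # per-lead slow residual around the trend


def _background_components(cfg: SimConfig, rng) -> _Components:
    labels = cfg.labels()
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    nc = cfg.noise
    broadband = np.empty((len(labels), n))
    for i in range(len(labels)):
        broadband[i] = nc.rms_uv * _pink_noise(
            rng, n, cfg.fs, nc.pink_exponent, floor_hz=nc.pink_floor_hz
        )
    if nc.common_osc_uv > 0:
        osc = nc.common_osc_uv * np.sin(
            2 * np.pi * nc.common_osc_hz * t + rng.uniform(0, 2 * np.pi)
        )
        broadband += osc
    trend = nc.trend_uv * _band_noise(rng, n, cfg.fs, 0.01, 0.4) if nc.trend_uv > 0 else np.zeros(n)
    # residual band starts at 0.05 Hz: slow enough to live in the Sv DC band,
    # fast enough to stay stationary over a few-hundred-second analysis span
    resid = np.empty((len(labels), n))
    for i in range(len(labels)):
        resid[i] = (
            nc.resid_svdc_uv * _band_noise(rng, n, cfg.fs, 0.05, 0.45)
            if nc.resid_svdc_uv > 0
            else 0.0
        )
    return _Components(broadband=broadband, trend=trend, resid=resid)


def generate_background(cfg: SimConfig, rng=None) -> Recording:
    """Interictal-style background only, reproducible from the config seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    comp = _background_components(cfg, rng)
    data = comp.broadband + comp.trend + comp.resid
    return Recording(data, fs=cfg.fs, labels=cfg.labels())


def _raised_cosine_step(t: np.ndarray, start: float, rise: float) -> np.ndarray:
    """0 before start, smooth raised-cosine rise to 1 over ``rise`` seconds."""
    x = np.clip((t - start) / max(rise, 1e-9), 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * x))


def _dc_waveform(
    t: np.ndarray, t_start: float, t_end: float, rise: float, fall: float
) -> np.ndarray:
    up = _raised_cosine_step(t, t_start, rise)
    down = _raised_cosine_step(t, t_end, fall)
    return up * (1 - down)


def inject_seizure(
    rec: Recording, cfg: SimConfig, rng=None
) -> tuple[Recording, SynthGroundTruth]:
    """Add a seizure to a background recording; returns truth latencies.

    Per lead: (i) a signed slow DC offset starting ``dc_lead_time_s`` before
    that lead's event time, largest on SOZ leads; (ii) rhythmic LF activity
    and (iii) an LVFA burst starting at the event time. Pathway mode stacks
    ``inter_lead_delay_s`` delays in spatial order; volume mode starts all
    leads together and ramps a common waveform into every lead.
    """
    cfg.validate()
    sz = cfg.seizure
    if sz is None:
        raise ParameterError("config has no seizure section")
    if sz.propagation not in ("pathway", "volume"):
        raise ParameterError(f"unknown propagation mode {sz.propagation!r}")
    if sz.onset_s + sz.duration_s > rec.duration:
        raise ParameterError("seizure extends past the end of the recording")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    labels = rec.labels
    missing = set(cfg.soz_leads) - set(labels)
    if missing:
        raise ParameterError(f"soz leads {sorted(missing)} not in recording")
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    t_end = sz.onset_s + sz.duration_s
    order = _spatial_order(labels)

    delays = {lab: 0.0 for lab in labels}
    if sz.propagation == "pathway":
        for pos, idx in enumerate(order):
            delays[labels[idx]] = pos * sz.inter_lead_delay_s

    # Signed per-lead DC amplitudes: leads disperse apart, SOZ largest.
    signs = rng.choice([-1.0, 1.0], size=len(labels))
    mags = sz.dc_shift_uv * rng.uniform(0.6, 1.6, size=len(labels))
    mags[[i for i, l in enumerate(labels) if l in cfg.soz_leads]] *= 1.5

    data = rec.data.copy()
    truth = SynthGroundTruth(
        seizure_onset_s=sz.onset_s,
        soz_leads=tuple(cfg.soz_leads),
        reconvergence_s=t_end + sz.dc_fall_s,
    )
    common_lf = np.sin(2 * np.pi * sz.lf_rhythm_hz * t + rng.uniform(0, 2 * np.pi))
    common_hf = _band_noise(rng, n, rec.fs, *sz.lvfa_band)
    ramp = np.clip((t - sz.onset_s) / sz.duration_s, 0.0, 1.0)
    ramp *= 1 - _raised_cosine_step(t, t_end, 2.0)  # common drive stops smoothly

    for i, lab in enumerate(labels):
        e_l = sz.onset_s + delays[lab]
        t_dc = e_l - sz.dc_lead_time_s
        truth.dc_onsets[lab] = t_dc
        truth.lf_onsets[lab] = e_l
        truth.hf_onsets[lab] = e_l
        data[i] += signs[i] * mags[i] * _dc_waveform(
            t, t_dc, t_end, sz.dc_rise_s, sz.dc_fall_s
        )
        env = _dc_waveform(t, e_l, t_end, 1.0, 2.0)  # fast on/off envelope
        if sz.propagation == "pathway":
            lf = sz.lf_amp_uv * np.sin(
                2 * np.pi * sz.lf_rhythm_hz * t + rng.uniform(0, 2 * np.pi)
            )
            hf = sz.lvfa_amp_uv * _band_noise(rng, n, rec.fs, *sz.lvfa_band)
            data[i] += env * (lf + hf)
        else:
            own_hf = sz.lvfa_amp_uv * _band_noise(rng, n, rec.fs, *sz.lvfa_band)
            data[i] += env * own_hf
            data[i] += ramp * sz.common_mix_uv * (common_lf + 0.3 * common_hf)

    out = rec.with_data(data)
    out.annotations.append(Annotation(sz.onset_s, sz.duration_s, "seizure"))
    return out, truth


def generate_ictal(cfg: SimConfig) -> tuple[Recording, SynthGroundTruth]:
    """Background plus one injected seizure, fully seeded from the config."""
    rng = np.random.default_rng(cfg.seed)
    rec = generate_background(cfg, rng=rng)
    return inject_seizure(rec, cfg, rng=rng)


def generate_interictal(cfg: SimConfig) -> tuple[Recording, SynthGroundTruth]:
    """Interictal recording with active intervals and SOZ-lead fluctuation.

    Background broadband energy is multiplied by ``active_gain`` (amplitude
    scaled by its square root) inside the configured active intervals, so the
    100%-over-baseline energy rule fires at the default gain of 4. The slow
    residual of SOZ leads is multiplied by ``soz_fluctuation_gain``; the
    shared slow trend is left untouched in both phases.
    """
    cfg.validate()
    ii = cfg.interictal
    intervals = sorted((float(a), float(b)) for a, b in ii.active_intervals)
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ParameterError(f"active intervals overlap: {(a0, a1)}, {(b0, b1)}")
    for a0, a1 in intervals:
        if not (0 <= a0 < a1 <= cfg.duration_s):
            raise ParameterError(f"active interval {(a0, a1)} outside the record")
    rng = np.random.default_rng(cfg.seed)
    comp = _background_components(cfg, rng)
    labels = cfg.labels()
    n = comp.broadband.shape[1]
    t = np.arange(n) / cfg.fs
    gain = np.ones(n)
    for a0, a1 in intervals:
        gain[(t >= a0) & (t < a1)] = np.sqrt(ii.active_gain)
    resid_gain = np.array(
        [ii.soz_fluctuation_gain if l in cfg.soz_leads else 1.0 for l in labels]
    )
    data = comp.broadband * gain + comp.trend + comp.resid * resid_gain[:, None]
    rec = Recording(data, fs=cfg.fs, labels=labels)
    truth = SynthGroundTruth(
        soz_leads=tuple(cfg.soz_leads), active_intervals=intervals
    )
    return rec, truth


def generate_study(
    configs: list[SimConfig], outdir, kind: str = "ictal"
) -> Path:
    """Write a small synthetic dataset: EDFs, truth JSON files, a manifest.

    Rerunning with the same configs reproduces the files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"kind": kind, "recordings": []}
    for k, cfg in enumerate(configs):
        if kind == "ictal":
            rec, truth = generate_ictal(cfg)
        elif kind == "interictal":
            rec, truth = generate_interictal(cfg)
        else:
            raise ParameterError(f"unknown study kind {kind!r}")
        stem = f"rec{k:03d}_seed{cfg.seed}"
        write_recording(rec, outdir / f"{stem}.edf", format="edf")
        (outdir / f"{stem}.truth.json").write_text(truth.to_json())
        manifest["recordings"].append(
            {"file": f"{stem}.edf", "seed": cfg.seed, "fs": cfg.fs,
             "duration_s": cfg.duration_s}
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
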