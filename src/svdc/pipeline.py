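"""End-to-end ictal and interictal analyses with plain-text reports.

Orchestrates the module chain: artifact flagging -> notch + broadband
preprocessing -> three-band decomposition -> energy ratios / dispersion /
onset ordering / staged propagation statistics (ictal), or sliding-window
phase detection, stable-vs-active comparison and lead ranking (interictal).
Every number in a report is produced by one library operation; reports are
tab-separated tables plus a JSON summary, reproducible from (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import decompose, extract_band, extract_svdc
from .dispersion import (
    detect_band_onset,
    detect_dispersion_onset,
    detect_reconvergence,
    onset_ordering,
    rank_leads_by_interictal_fluctuation,
    svdc_dispersion,
)
from .energy import (
    compare_phase_energy,
    detect_active_phases,
    energy_ratio,
    ictal_window,
    preceding_hour_baseline,
    sliding_energy,
    threshold_summary,
)
from .errors import ParameterError
from .io import Recording
from .network import stage_summaries, staged_cross_correlation, staged_plv
from .preprocess import broadband_filter, flag_artifact_channels, notch_filter

__all__ = [
    "IctalParams",
    "InterictalParams",
    "AnalysisReport",
    "preprocess_recording",
    "run_ictal_analysis",
    "run_interictal_analysis",
]


@dataclass
class IctalParams:
    """Tunables of the ictal analysis (defaults follow the module specs)."""

    notch_hz: float = 50.0
    band: tuple[float, float] = (0.01, 300.0)
    pre_s: float = 120.0
    post_s: float = 120.0
    hour_s: float = 3600.0
    thresholds: tuple[float, ...] = (0.6, 0.9)
    disp_window_s: float = 2.0
    k: float = 3.0
    min_dur_s: float = 10.0
    ref_interval: tuple[float, float] | None = None  # default: ends 30 s pre-window
    n_stages: int = 3
    seizure_duration_s: float = 90.0  # staged-analysis span after onset
    plv_band: str = "hf"
    cc_band: tuple[float, float] = (0.5, 300.0)
    cc_pair: tuple[str, str] | None = None


@dataclass
class InterictalParams:
    notch_hz: float = 50.0
    band: tuple[float, float] = (0.01, 300.0)
    window_s: float = 6.0
    increase: float = 1.0
    min_dur_s: float = 12.0
    merge_gap_s: float = 6.0
    history_s: float = 3600.0
    edge_guard_s: float = 12.0  # keep filter edge transients out of the span


@dataclass
class AnalysisReport:
    """Tables plus scalars plus provenance; writable as TSV + JSON."""

    tables: dict = field(default_factory=dict)  # name -> DataFrame
    scalars: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        summary = {
            "scalars": self.scalars,
            "notes": self.notes,
            "provenance": self.provenance,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=_jsonable)
        )
        return outdir


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _provenance(params, rec: Recording, extra: dict | None = None) -> dict:
    out = {
        "package_version": __version__,
        "params": dataclasses.asdict(params),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "fs": rec.fs,
    }
    if extra:
        out.update(extra)
    return out


def preprocess_recording(
    rec: Recording,
    notch_hz: float,
    band: tuple[float, float],
    quality_span: tuple[float, float] | None = None,
) -> tuple[Recording, list[str]]:
    """Flag artifact channels, then notch + broadband filter.

    Channel quality is judged on ``quality_span`` when given (the ictal
    pipeline passes the pre-onset background, since a genuine ictal DC shift
    would otherwise trip the drift rule that targets electrode artifacts).
    Returns the fully filtered recording, the notch-only recording (used for
    the Sv DC timing analyses: the zero-phase 0.01 Hz high-pass smears large
    slow transients tens of seconds backward in time, which would bias onset
    latencies), and the flagged-label list. All channels are retained;
    flagged ones are only masked from downstream statistics.
    """
    probe = rec
    if quality_span is not None:
        i0, i1 = rec.sample_slice(*quality_span)
        if (i1 - i0) / rec.fs >= 30.0:
            probe = rec.with_data(rec.data[:, i0:i1])
    quality = flag_artifact_channels(probe)
    flagged = [q.label for q in quality if not q.retained]
    notched = notch_filter(rec, freq_hz=notch_hz)
    clean = broadband_filter(notched, *band)
    return clean, notched, flagged


def run_ictal_analysis(
    rec: Recording, onset_s: float, params: IctalParams | None = None
) -> AnalysisReport:
    """Full peri-ictal analysis of one seizure.

    Produces the 4-min and ~1-h energy summaries with threshold fractions,
    the Sv DC dispersion trace with detected onset/peak/reconvergence, LF and
    HF band onsets with the ordering report, and the staged cross-correlation
    and PLV propagation statistics.
    """
    p = params or IctalParams()
    report = AnalysisReport(provenance=_provenance(p, rec, {"onset_s": onset_s}))
    dc_guard = 60.0  # keep the pre-ictal Sv DC ramp out of the quality probe
    qspan = (0.0, onset_s - dc_guard) if onset_s - dc_guard >= 30.0 else None
    clean, notched, flagged = preprocess_recording(
        rec, p.notch_hz, p.band, quality_span=qspan
    )
    report.scalars["n_flagged"] = len(flagged)
    report.scalars["flagged"] = ",".join(flagged)
    usable = [l for l in rec.labels if l not in flagged]
    if len(usable) < 2:
        report.notes.append("fewer than 2 usable channels; analysis skipped")
        return report

    t0, t1 = ictal_window(onset_s, p.pre_s, p.post_s, record_duration=rec.duration)
    bands = decompose(clean)
    summary_ictal = energy_ratio(clean, bands, t0, t1, exclude=tuple(flagged))
    report.tables["energy_ictal"] = summary_ictal.per_lead
    report.tables["threshold_fractions_ictal"] = threshold_summary(
        summary_ictal, p.thresholds
    )
    h0 = max(0.0, onset_s - p.hour_s / 2)
    h1 = min(rec.duration, onset_s + p.hour_s / 2)
    if h1 - h0 < p.hour_s:
        report.notes.append(
            f"hour window clipped to [{h0:.0f}, {h1:.0f}) s (record too short)"
        )
    summary_hour = energy_ratio(clean, bands, h0, h1, exclude=tuple(flagged))
    report.tables["energy_hour"] = summary_hour.per_lead
    report.tables["threshold_fractions_hour"] = threshold_summary(
        summary_hour, p.thresholds
    )

    ref = p.ref_interval or (max(0.0, t0 - 150.0), max(0.0, t0 - 30.0))
    keep_idx = [i for i, l in enumerate(rec.labels) if l not in flagged]
    # timing analyses use the notch-only Sv DC (no 0.01 Hz high-pass smear)
    svdc = extract_svdc(notched)[keep_idx]
    trace = svdc_dispersion(svdc, rec.fs, ref, window_s=p.disp_window_s)
    disp_onset = detect_dispersion_onset(trace, k=p.k, min_dur_s=p.min_dur_s)
    detect_reconvergence(trace, k=p.k, min_dur_s=p.min_dur_s)
    baseline_iv = ref
    lf_onset = detect_band_onset(
        bands.lf[keep_idx], rec.fs, window_s=p.disp_window_s, k=p.k,
        min_dur_s=p.min_dur_s, baseline_interval=baseline_iv,
    )
    hf_onset = detect_band_onset(
        bands.hf[keep_idx], rec.fs, window_s=p.disp_window_s, k=p.k,
        min_dur_s=p.min_dur_s, baseline_interval=baseline_iv,
    )
    ordering = onset_ordering(disp_onset, lf_onset, hf_onset)
    report.tables["dispersion_trace"] = pd.DataFrame(
        {"time_s": trace.times, "dispersion_uv": trace.values}
    )
    report.scalars.update(
        {
            "dispersion_onset_s": disp_onset,
            "dispersion_peak_s": trace.peak_s,
            "reconvergence_s": trace.reconvergence_s,
            "lf_onset_s": lf_onset,
            "hf_onset_s": hf_onset,
            "latency_svdc_to_lf_s": ordering.latency_svdc_to_lf,
            "latency_svdc_to_hf_s": ordering.latency_svdc_to_hf,
            "svdc_first": ordering.svdc_first,
        }
    )

    span = (onset_s, min(onset_s + p.seizure_duration_s, rec.duration))
    pair = p.cc_pair or _default_cc_pair(svdc, [rec.labels[i] for i in keep_idx], rec.fs, ref, span)
    cc_band_sig = extract_band(clean, *p.cc_band)
    i1_, i2_ = rec.labels.index(pair[0]), rec.labels.index(pair[1])
    cc = staged_cross_correlation(
        cc_band_sig[i1_], cc_band_sig[i2_], rec.fs, span, p.n_stages
    )
    report.tables["staged_cross_correlation"] = pd.DataFrame(
        {
            "stage_t0": [s[0] for s in cc.stages],
            "stage_t1": [s[1] for s in cc.stages],
            "rho": cc.values,
        }
    )
    report.scalars["cc_pair"] = f"{pair[0]},{pair[1]}"

    plv_series = staged_plv(
        bands.band(p.plv_band), rec.labels, rec.fs, span, p.n_stages,
        band=p.plv_band, exclude=tuple(flagged),
    )
    report.tables["staged_plv_mean"] = pd.DataFrame(
        {
            "stage_t0": [s[0] for s in plv_series.stages],
            "stage_t1": [s[1] for s in plv_series.stages],
            "mean_offdiag_plv": stage_summaries(plv_series),
        }
    )
    return report


def _default_cc_pair(
    svdc: np.ndarray, labels: list[str], fs: float,
    ref: tuple[float, float], span: tuple[float, float],
) -> tuple[str, str]:
    """Lead pair for staged correlation: largest vs smallest ictal Sv DC shift.

    Mirrors comparing a seizure-onset-zone contact against a distant contact.
    """
    i0 = int(round(ref[0] * fs))
    i1 = max(i0 + 1, int(round(ref[1] * fs)))
    ref_mean = svdc[:, i0:i1].mean(axis=1)
    j0 = int(round(span[0] * fs))
    j1 = max(j0 + 1, min(int(round(span[1] * fs)), svdc.shape[1]))
    shift = np.abs(svdc[:, j0:j1].mean(axis=1) - ref_mean)
    return labels[int(np.argmax(shift))], labels[int(np.argmin(shift))]


def run_interictal_analysis(
    rec: Recording,
    observation_span: tuple[float, float] | None = None,
    params: InterictalParams | None = None,
) -> AnalysisReport:
    """Interictal analysis: phases, stable-vs-active energies, lead ranking.

    The baseline is the mean 6-s window energy over the hour preceding the
    observation span (clipped with a note when less history exists). Phases
    are detected on the cross-lead mean energy trace; the rank-sum comparison
    is run per lead and pooled; leads are ranked by Sv DC fluctuation.
    """
    p = params or InterictalParams()
    report = AnalysisReport(provenance=_provenance(p, rec))
    clean, notched, flagged = preprocess_recording(rec, p.notch_hz, p.band)
    report.scalars["n_flagged"] = len(flagged)
    usable_idx = [i for i, l in enumerate(rec.labels) if l not in flagged]
    if len(usable_idx) < 3:
        report.notes.append("fewer than 3 usable channels; analysis skipped")
        return report
    labels = [rec.labels[i] for i in usable_idx]
    x = clean.data[usable_idx]

    if observation_span is None:
        observation_span = (rec.duration / 2, rec.duration)
    t_obs0, t_obs1 = observation_span
    if not (0 < t_obs0 < t_obs1 <= rec.duration + 1e-9):
        raise ParameterError(f"bad observation span {observation_span}")
    guarded = min(t_obs1, rec.duration - p.edge_guard_s)
    if guarded < t_obs1:
        report.notes.append(
            f"observation span end moved to {guarded:.0f} s to keep filter "
            "edge transients out of the energy trace"
        )
        t_obs1 = guarded
    if t_obs0 < p.history_s:
        report.notes.append(
            f"baseline clipped to {t_obs0:.0f} s of history (less than "
            f"{p.history_s:.0f} s recorded before the observation span)"
        )
    # baseline = mean over leads of each lead's preceding-hour window energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_lead_baseline = [
            preceding_hour_baseline(xi, rec.fs, t_obs0, p.window_s, p.history_s)
            for xi in x
        ]
    baseline = float(np.mean(per_lead_baseline))

    i0, i1 = clean.sample_slice(t_obs0, t_obs1)
    traces = sliding_energy(x[:, i0:i1], rec.fs, window_s=p.window_s, t_offset=t_obs0)
    mean_trace = dataclasses.replace(traces, values=traces.values.mean(axis=0))
    phases = detect_active_phases(
        mean_trace, baseline, increase=p.increase,
        min_dur_s=p.min_dur_s, merge_gap_s=p.merge_gap_s,
    )
    report.tables["phases"] = pd.DataFrame(
        [("active", a, b) for a, b in phases.active]
        + [("stable", a, b) for a, b in phases.stable],
        columns=["phase", "t0_s", "t1_s"],
    )
    report.scalars["baseline_energy"] = baseline
    report.scalars["n_active_intervals"] = len(phases.active)

    def _in_phase(intervals):
        mask = np.zeros(traces.values.shape[1], dtype=bool)
        centers = traces.times + p.window_s / 2
        for a, b in intervals:
            mask |= (centers >= a) & (centers < b)
        return mask

    act_mask, stab_mask = _in_phase(phases.active), _in_phase(phases.stable)
    rows = []
    pooled_a, pooled_s = [], []
    for lab, vals in zip(labels, traces.values):
        a, s = vals[act_mask], vals[stab_mask]
        pooled_a.append(a)
        pooled_s.append(s)
        if a.size >= 3 and s.size >= 3:
            cmp = compare_phase_energy(s, a)
            rows.append((lab, cmp.median_stable, cmp.median_active,
                         cmp.statistic, cmp.pvalue, cmp.active_higher))
        else:
            rows.append((lab, float(np.median(s)) if s.size else np.nan,
                         float(np.median(a)) if a.size else np.nan,
                         np.nan, np.nan, False))
    report.tables["phase_comparison"] = pd.DataFrame(
        rows,
        columns=["lead", "median_stable", "median_active", "ranksum_stat",
                 "p_value", "active_higher"],
    )
    pa, ps = np.concatenate(pooled_a), np.concatenate(pooled_s)
    if pa.size >= 3 and ps.size >= 3:
        pooled = compare_phase_energy(ps, pa)
        report.scalars["pooled_p_value"] = pooled.pvalue
        report.scalars["pooled_active_higher"] = pooled.active_higher
    else:
        report.scalars["pooled_p_value"] = None
        report.notes.append("no active phase detected; pooled comparison skipped")

    svdc = extract_svdc(notched)[usable_idx][:, i0:i1]
    if len(labels) >= 3:
        scores = rank_leads_by_interictal_fluctuation(svdc, labels, fs=rec.fs)
        report.tables["lead_ranking"] = pd.DataFrame(
            {
                "lead": [s.lead for s in scores],
                "score_uv": [s.score for s in scores],
                "rank": [s.rank for s in scores],
            }
        )
    return report
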