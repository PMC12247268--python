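"""Cross-lead Sv DC dispersion, onset detection, and lead ranking.

The central observable is *dispersion*: after each lead's Sv DC trace is
referenced to its own pre-ictal baseline mean, dispersion(t) is the standard
deviation across leads of the referenced traces, evaluated per 2-second
window. A shared shift of the whole field leaves dispersion unchanged; only
leads diverging from each other raise it.

Onset detection uses robust baseline statistics (median + k * MAD from a
reference interval) with a sustained-run requirement, because ictal values
are extreme outliers relative to baseline. The same rule applied to a band's
sliding energy gives LF/HF onsets, allowing the "Sv DC disperses before the
LF and HF activity starts" ordering to be measured rather than eyeballed.

Interictally, leads are ranked by how strongly their Sv DC fluctuates around
the shared cross-lead trend (median across leads); epileptogenic-zone leads
are expected at the top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .energy import sliding_energy
from .errors import ParameterError

__all__ = [
    "DispersionTrace",
    "LeadFluctuationScore",
    "OnsetOrdering",
    "svdc_dispersion",
    "detect_dispersion_onset",
    "detect_reconvergence",
    "detect_band_onset",
    "onset_ordering",
    "rank_leads_by_interictal_fluctuation",
]


@dataclass
class DispersionTrace:
    """Time-resolved cross-lead Sv DC spread with baseline statistics."""

    times: np.ndarray  # window centres, s
    values: np.ndarray  # cross-lead SD, uV
    window_s: float
    baseline_median: float
    baseline_mad: float
    onset_s: float | None = None
    peak_s: float | None = None
    reconvergence_s: float | None = None


def svdc_dispersion(
    svdc: np.ndarray,
    fs: float,
    ref_interval: tuple[float, float],
    window_s: float = 2.0,
    robust: bool = False,
) -> DispersionTrace:
    """Cross-lead spread of baseline-referenced Sv DC, per 2-s window.

    Each lead is referenced by subtracting its mean over ``ref_interval``;
    the trace value at a window is the population SD across leads of the
    per-lead window means (or 1.4826 * MAD with ``robust=True``). Baseline
    median/MAD are taken from the windows inside ``ref_interval``.
    """
    x = np.atleast_2d(np.asarray(svdc, dtype=float))
    if x.shape[0] < 2:
        raise ParameterError("dispersion needs at least 2 leads")
    r0, r1 = ref_interval
    if not 0 <= r0 < r1:
        raise ParameterError(f"bad reference interval {ref_interval}")
    i0 = int(round(r0 * fs))
    i1 = min(int(round(r1 * fs)), x.shape[1])
    if i1 - i0 < 2:
        raise ParameterError("reference interval contains too few samples")
    ref_mean = x[:, i0:i1].mean(axis=1, keepdims=True)
    xr = x - ref_mean

    w = max(1, int(round(window_s * fs)))
    n_win = x.shape[1] // w
    if n_win < 1:
        raise ParameterError("record shorter than one dispersion window")
    means = xr[:, : n_win * w].reshape(x.shape[0], n_win, w).mean(axis=2)
    if robust:
        med = np.median(means, axis=0)
        values = 1.4826 * np.median(np.abs(means - med), axis=0)
    else:
        values = means.std(axis=0, ddof=0)
    times = (np.arange(n_win) + 0.5) * w / fs

    in_ref = (times >= r0) & (times < r1)
    base = values[in_ref]
    if base.size == 0:
        base = values[: max(1, n_win // 10)]
    bmed = float(np.median(base))
    bmad = float(np.median(np.abs(base - bmed)))
    trace = DispersionTrace(
        times=times,
        values=values,
        window_s=w / fs,
        baseline_median=bmed,
        baseline_mad=bmad,
    )
    trace.peak_s = float(times[int(np.argmax(values))])
    return trace


def _sustained_crossing(
    times: np.ndarray,
    above: np.ndarray,
    window_s: float,
    min_dur_s: float,
    start_idx: int = 0,
) -> float | None:
    """Start time of the first run of True lasting >= min_dur_s."""
    need = max(1, int(np.ceil(min_dur_s / window_s)))
    run = 0
    for i in range(start_idx, above.size):
        run = run + 1 if above[i] else 0
        if run >= need:
            return float(times[i - need + 1] - window_s / 2)
    return None


def _threshold(trace: DispersionTrace, k: float, floor: float) -> float:
    mad = trace.baseline_mad
    if mad <= 0:
        if floor <= 0:
            warnings.warn(
                "baseline MAD is zero and no absolute floor given; threshold "
                "degenerates to the baseline median",
                stacklevel=3,
            )
        mad = 0.0
    return trace.baseline_median + max(k * mad, floor)


def detect_dispersion_onset(
    trace: DispersionTrace,
    k: float = 3.0,
    min_dur_s: float = 10.0,
    floor: float = 0.0,
) -> float | None:
    """Earliest sustained excursion of dispersion above baseline.

    Onset = start of the first run of windows with value > median + k * MAD
    lasting at least ``min_dur_s``; None when no such run exists. With a
    zero-MAD baseline the configurable absolute ``floor`` (uV) replaces the
    MAD term. The trace's ``onset_s`` field is filled in as a side effect.
    """
    thr = _threshold(trace, k, floor)
    onset = _sustained_crossing(
        trace.times, trace.values > thr, trace.window_s, min_dur_s
    )
    trace.onset_s = onset
    return onset


def detect_reconvergence(
    trace: DispersionTrace,
    k: float = 3.0,
    min_dur_s: float = 10.0,
    floor: float = 0.0,
) -> float | None:
    """First sustained return of dispersion to baseline after its peak.

    The dispersed field "re-converging" is detected as the first run of
    windows at/below the onset threshold, lasting ``min_dur_s`` or reaching
    the end of the trace, after the peak. Fills ``reconvergence_s``.
    """
    if trace.peak_s is None:
        return None
    thr = _threshold(trace, k, floor)
    below = trace.values <= thr
    start = int(np.searchsorted(trace.times, trace.peak_s))
    need = max(1, int(np.ceil(min_dur_s / trace.window_s)))
    run = 0
    for i in range(start, below.size):
        run = run + 1 if below[i] else 0
        if run >= need or (below[i] and i == below.size - 1 and run > 0):
            trace.reconvergence_s = float(
                trace.times[i - run + 1] - trace.window_s / 2
            )
            return trace.reconvergence_s
    trace.reconvergence_s = None
    return None


def detect_band_onset(
    series: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    k: float = 3.0,
    min_dur_s: float = 10.0,
    baseline_interval: tuple[float, float] | None = None,
    floor: float = 0.0,
) -> float | None:
    """Onset of sustained energy increase in one band.

    The band series (1-D, or 2-D in which case the cross-lead mean energy is
    used) is converted to a sliding-energy trace; the same median + k * MAD
    sustained-run rule as for dispersion is applied. ``baseline_interval``
    defaults to the first quarter of the record.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    trace = sliding_energy(x, fs, window_s=window_s)
    values = trace.values.mean(axis=0)
    times = trace.times + window_s / 2
    duration = x.shape[-1] / fs
    b0, b1 = baseline_interval if baseline_interval else (0.0, duration / 4)
    in_base = (times >= b0) & (times < b1)
    base = values[in_base] if in_base.any() else values[: max(1, values.size // 4)]
    bmed = float(np.median(base))
    bmad = float(np.median(np.abs(base - bmed)))
    dtrace = DispersionTrace(
        times=times,
        values=values,
        window_s=window_s,
        baseline_median=bmed,
        baseline_mad=bmad,
    )
    return detect_dispersion_onset(dtrace, k=k, min_dur_s=min_dur_s, floor=floor)


@dataclass
class OnsetOrdering:
    """Pairwise latencies between the Sv DC dispersion onset and band onsets."""

    svdc_onset_s: float | None
    lf_onset_s: float | None
    hf_onset_s: float | None
    latency_svdc_to_lf: float | None
    latency_svdc_to_hf: float | None
    svdc_first: bool


def onset_ordering(
    svdc_onset: float | None, lf_onset: float | None, hf_onset: float | None
) -> OnsetOrdering:
    """Latency report: does Sv DC dispersion lead the LF/HF activity?

    ``svdc_first`` is True only when the dispersion onset exists and is
    strictly earlier than every present band onset.
    """
    if svdc_onset is None and lf_onset is None and hf_onset is None:
        raise ParameterError("at least one onset must be present")
    lat_lf = None if (svdc_onset is None or lf_onset is None) else lf_onset - svdc_onset
    lat_hf = None if (svdc_onset is None or hf_onset is None) else hf_onset - svdc_onset
    others = [o for o in (lf_onset, hf_onset) if o is not None]
    first = svdc_onset is not None and all(svdc_onset < o for o in others) and bool(others)
    return OnsetOrdering(svdc_onset, lf_onset, hf_onset, lat_lf, lat_hf, first)


@dataclass
class LeadFluctuationScore:
    """Residual Sv DC fluctuation of one lead around the shared trend."""

    lead: str
    score: float
    rank: int


def rank_leads_by_interictal_fluctuation(
    svdc: np.ndarray,
    labels: list[str],
    fs: float | None = None,
    min_span_s: float = 600.0,
) -> list[LeadFluctuationScore]:
    """Rank leads by Sv DC fluctuation around the cross-lead median trend.

    The shared trend is the sample-wise *median* across leads, so one extreme
    (epileptogenic) lead cannot drag the trend it is scored against. Score =
    SD of (lead - trend); descending ranks, rank 1 = strongest fluctuation.
    Requires at least 3 leads. When leads carry similar noise the scores tie
    within sampling error and the ranking is not meaningful — callers should
    look at score contrasts, not bare ranks.
    """
    x = np.atleast_2d(np.asarray(svdc, dtype=float))
    if x.shape[0] < 3:
        raise ParameterError("lead ranking needs at least 3 leads")
    if len(labels) != x.shape[0]:
        raise ParameterError("labels do not match the number of leads")
    if fs is not None and x.shape[1] / fs < min_span_s:
        warnings.warn(
            f"interictal span shorter than {min_span_s:.0f} s; fluctuation "
            "scores may be unstable",
            stacklevel=2,
        )
    trend = np.median(x, axis=0)
    scores = (x - trend).std(axis=1, ddof=0)
    order = np.argsort(-scores, kind="stable")
    out = [None] * x.shape[0]
    for rank0, idx in enumerate(order):
        out[rank0] = LeadFluctuationScore(
            lead=labels[idx], score=float(scores[idx]), rank=rank0 + 1
        )
    return out
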