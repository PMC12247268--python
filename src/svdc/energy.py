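"""Energy-ratio statistics and interictal active/stable phase machinery.

Energy is the time-domain sum of squared samples (uV^2 * samples) — never a
spectral estimate. The headline statistic is the Sv DC energy ratio: the Sv DC
component's energy divided by the total energy of the full preprocessed
(0.01-300 Hz) signal over the same window, per lead. Threshold summaries count
the leads whose ratio reaches 60% / 90%, mirroring the reported seizure-level
fractions.

Interictal machinery: 6-second sliding-window energy, a baseline taken as the
mean window energy over the preceding hour, and "active" phases defined as
runs of windows whose energy exceeds the baseline by at least 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandSet
from .errors import ParameterError
from .io import Recording

__all__ = [
    "EnergySummary",
    "EnergyTrace",
    "PhaseIntervals",
    "PhaseComparison",
    "segment_energy",
    "energy_ratio",
    "ictal_window",
    "threshold_summary",
    "sliding_energy",
    "detect_active_phases",
    "preceding_hour_baseline",
    "compare_phase_energy",
]


def _slice_idx(n: int, fs: float, t0: float, t1: float) -> tuple[int, int]:
    if t1 <= t0:
        raise ParameterError(f"empty window [{t0}, {t1})")
    eps = 1e-9
    i0 = max(int(np.ceil(t0 * fs - eps)), 0)
    i1 = min(int(np.ceil(t1 * fs - eps)), n)
    if i1 <= i0:
        raise ParameterError(f"window [{t0}, {t1}) contains no samples")
    return i0, i1


def segment_energy(series: np.ndarray, fs: float, t0: float, t1: float) -> np.ndarray:
    """Sum of squared samples over the half-open window ``[t0, t1)``.

    ``series`` may be 1-D (one lead) or 2-D (leads x samples); the result has
    one value per lead. Additive over disjoint windows.
    """
    x = np.asarray(series, dtype=float)
    i0, i1 = _slice_idx(x.shape[-1], fs, t0, t1)
    out = np.sum(np.square(x[..., i0:i1]), axis=-1)
    return out


@dataclass
class EnergySummary:
    """Per-lead band energies and ratios for one named window."""

    window: tuple[float, float]
    per_lead: pd.DataFrame  # lead, E_total, E_svdc, E_lf, E_hf, ratio_*
    n_excluded: int = 0
    threshold_fractions: dict = field(default_factory=dict)


def energy_ratio(
    rec: Recording,
    bands: BandSet,
    t0: float,
    t1: float,
    exclude: tuple[str, ...] = (),
) -> EnergySummary:
    """Band energy ratios over ``[t0, t1)``, one row per retained lead.

    The denominator is the energy of the full preprocessed signal (``rec``),
    not the sum of the three band energies. Leads in ``exclude`` (artifact
    flags) are dropped from the table; zero-total-energy leads get missing
    (NaN) ratios rather than 0.
    """
    if rec.data.shape != bands.svdc.shape or rec.fs != bands.source_fs:
        raise ParameterError("bandset is not aligned with the recording")
    keep = [i for i, lab in enumerate(rec.labels) if lab not in exclude]
    e_total = segment_energy(rec.data[keep], rec.fs, t0, t1)
    e_svdc = segment_energy(bands.svdc[keep], rec.fs, t0, t1)
    e_lf = segment_energy(bands.lf[keep], rec.fs, t0, t1)
    e_hf = segment_energy(bands.hf[keep], rec.fs, t0, t1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(e_total > 0, e_total, np.nan)
        df = pd.DataFrame(
            {
                "lead": [rec.labels[i] for i in keep],
                "E_total": e_total,
                "E_svdc": e_svdc,
                "E_lf": e_lf,
                "E_hf": e_hf,
                "ratio_svdc": e_svdc / denom,
                "ratio_lf": e_lf / denom,
                "ratio_hf": e_hf / denom,
            }
        )
    return EnergySummary(
        window=(t0, t1), per_lead=df, n_excluded=rec.n_channels - len(keep)
    )


def ictal_window(
    onset_s: float,
    pre_s: float = 120.0,
    post_s: float = 120.0,
    record_duration: float | None = None,
) -> tuple[float, float]:
    """Analysis window spanning ``pre_s`` before to ``post_s`` after onset.

    Defaults give the 4-minute peri-ictal segment (2 min before and 2 min
    after onset). Clipped to the record with a warning when a duration is
    supplied; an onset outside the record is an error.
    """
    if onset_s < 0 or (record_duration is not None and onset_s > record_duration):
        raise ParameterError(f"onset {onset_s} s outside the record")
    t0, t1 = onset_s - pre_s, onset_s + post_s
    if record_duration is not None and (t0 < 0 or t1 > record_duration):
        warnings.warn(
            f"ictal window [{t0:.1f}, {t1:.1f}) clipped to the record", stacklevel=2
        )
        t0, t1 = max(t0, 0.0), min(t1, record_duration)
    elif t0 < 0:
        warnings.warn(f"ictal window start {t0:.1f} clipped to 0", stacklevel=2)
        t0 = 0.0
    return t0, t1


def threshold_summary(summaries, thresholds=(0.6, 0.9)) -> pd.DataFrame:
    """Counts and fractions of leads with Sv DC ratio >= each threshold.

    ``summaries`` may be one :class:`EnergySummary`, an iterable of them
    (pooled across recordings/seizures), or a bare array of per-lead Sv DC
    ratios. Comparisons are inclusive (>=). Leads with missing ratios are
    excluded from the denominator and reported in ``n_missing``.
    """
    if isinstance(summaries, EnergySummary):
        ratios = summaries.per_lead["ratio_svdc"].to_numpy()
    else:
        items = list(summaries) if not isinstance(summaries, np.ndarray) else summaries
        if len(items) and isinstance(items[0], EnergySummary):
            ratios = np.concatenate(
                [s.per_lead["ratio_svdc"].to_numpy() for s in items]
            )
        else:
            ratios = np.asarray(items, dtype=float).ravel()
    n_missing = int(np.sum(~np.isfinite(ratios)))
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ParameterError("no leads with defined Sv DC ratios")
    rows = []
    for thr in sorted(thresholds):
        count = int(np.sum(ratios >= thr))
        rows.append(
            {
                "threshold": thr,
                "count": count,
                "n": int(ratios.size),
                "n_missing": n_missing,
                "fraction": count / ratios.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnergyTrace:
    """Sliding-window energies with their window start times."""

    times: np.ndarray  # window start times, s
    values: np.ndarray  # per-window sum of squares
    window_s: float
    hop_s: float

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1] + self.window_s)


def sliding_energy(
    series: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    hop_s: float | None = None,
    t_offset: float = 0.0,
) -> EnergyTrace:
    """Per-window sum of squares over a sliding window.

    Default hop equals the window (non-overlapping tiling). ``series`` may be
    1-D or 2-D (leads x samples); 2-D input yields a ``(n_leads, n_windows)``
    value array. Only complete windows are emitted.
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    hop_s = window_s if hop_s is None else hop_s
    if hop_s <= 0:
        raise ParameterError(f"hop_s must be positive, got {hop_s}")
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    w = int(round(window_s * fs))
    h = max(1, int(round(hop_s * fs)))
    if n < w:
        raise ParameterError(f"record ({n} samples) shorter than window ({w})")
    starts = np.arange(0, n - w + 1, h)
    cs = np.cumsum(np.square(x), axis=-1)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), cs], axis=-1)
    values = cs[..., starts + w] - cs[..., starts]
    return EnergyTrace(
        times=t_offset + starts / fs, values=values, window_s=window_s, hop_s=hop_s
    )


@dataclass
class PhaseIntervals:
    """Active/stable partition of an analyzed span.

    ``criterion`` is the fractional energy increase over baseline that defines
    "active" (1.0 = the 100% rule).
    """

    baseline_energy: float
    active: list[tuple[float, float]]
    stable: list[tuple[float, float]]
    window_s: float
    criterion: float

    @property
    def span(self) -> tuple[float, float]:
        pieces = self.active + self.stable
        return min(p[0] for p in pieces), max(p[1] for p in pieces)


def detect_active_phases(
    trace: EnergyTrace,
    baseline: float,
    increase: float = 1.0,
    min_dur_s: float = 12.0,
    merge_gap_s: float = 6.0,
) -> PhaseIntervals:
    """Partition a window-energy trace into active and stable phases.

    Active = maximal runs of windows with energy >= ``(1 + increase) *
    baseline`` (inclusive threshold). Runs shorter than ``min_dur_s`` are
    dropped, then surviving runs separated by less than ``merge_gap_s`` are
    merged. The stable phase is the complement over the analyzed span.
    """
    if baseline <= 0:
        raise ParameterError(f"baseline must be positive, got {baseline}")
    values = np.asarray(trace.values, dtype=float)
    if values.ndim != 1:
        raise ParameterError("detect_active_phases expects a 1-D energy trace")
    hot = values >= (1.0 + increase) * baseline
    intervals = []
    for i0, i1 in _bool_runs(hot):
        t0 = float(trace.times[i0])
        t1 = float(trace.times[i1 - 1] + trace.window_s)
        if t1 - t0 >= min_dur_s:
            intervals.append((t0, t1))
    merged: list[tuple[float, float]] = []
    for t0, t1 in intervals:
        if merged and t0 - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], t1)
        else:
            merged.append((t0, t1))
    span0, span1 = trace.span
    stable = []
    cursor = span0
    for t0, t1 in merged:
        if t0 > cursor:
            stable.append((cursor, t0))
        cursor = t1
    if cursor < span1:
        stable.append((cursor, span1))
    return PhaseIntervals(
        baseline_energy=float(baseline),
        active=merged,
        stable=stable,
        window_s=trace.window_s,
        criterion=increase,
    )


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def preceding_hour_baseline(
    series: np.ndarray,
    fs: float,
    t_obs: float,
    window_s: float = 6.0,
    history_s: float = 3600.0,
) -> float:
    """Mean sliding-window energy over the hour preceding ``t_obs``.

    Clips to the available history with a warning when less than an hour is
    recorded before the observation start; no history at all is an error.
    """
    if t_obs <= 0:
        raise ParameterError("no history before t_obs = 0")
    x = np.asarray(series, dtype=float)
    t0 = t_obs - history_s
    if t0 < 0:
        warnings.warn(
            f"only {t_obs:.0f} s of history before the observation period; "
            "baseline clipped",
            stacklevel=2,
        )
        t0 = 0.0
    i0, i1 = _slice_idx(x.shape[-1], fs, t0, t_obs)
    if (i1 - i0) / fs < window_s:
        raise ParameterError("history shorter than one baseline window")
    trace = sliding_energy(x[..., i0:i1], fs, window_s=window_s)
    return float(np.mean(trace.values))


@dataclass
class PhaseComparison:
    """Wilcoxon rank-sum comparison of stable vs active window energies."""

    statistic: float
    pvalue: float
    median_stable: float
    median_active: float
    active_higher: bool


def compare_phase_energy(stable_energies, active_energies) -> PhaseComparison:
    """Two-sided Wilcoxon rank-sum test on two window-energy samples.

    Samples of size < 3 yield a warning and a missing (NaN) p-value.
    """
    s = np.asarray(stable_energies, dtype=float)
    a = np.asarray(active_energies, dtype=float)
    if s.size == 0 or a.size == 0:
        raise ParameterError("both phase-energy samples must be non-empty")
    med_s, med_a = float(np.median(s)), float(np.median(a))
    if s.size < 3 or a.size < 3:
        warnings.warn("phase-energy sample smaller than 3; p-value undefined",
                      stacklevel=2)
        return PhaseComparison(np.nan, np.nan, med_s, med_a, med_a > med_s)
    res = stats.ranksums(a, s)
    return PhaseComparison(
        float(res.statistic), float(res.pvalue), med_s, med_a, med_a > med_s
    )
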