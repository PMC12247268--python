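"""Correlation and phase-synchronization propagation analysis.

Three primitives drive the propagation analysis:

* autocorrelation  rho(tau) = sum s(t) s(t+tau) / sum s(t)^2, the lag sum
  taken over the overlapping support and normalized by the full-signal
  energy (so rho(0) = 1 exactly);
* the mean-centred normalized cross-correlation rho_12 in [-1, 1];
* the phase-locking value PLV = |mean exp(j * dtheta)| in [0, 1], with
  instantaneous phases taken from the analytic (Hilbert) signal of a
  band-limited series.

Staged variants split a seizure span into equal stages (default thirds) and
evaluate the statistic per stage: propagation by volume conduction shows
cross-lead correlation rising toward 1 in the late stages, while pathway
propagation recruits leads one by one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

__all__ = [
    "PLVMatrix",
    "StageSeries",
    "autocorrelation",
    "cross_correlation",
    "staged_cross_correlation",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "staged_plv",
]


def autocorrelation(s: np.ndarray, tau_s: float, fs: float) -> float:
    """Normalized autocorrelation at lag ``tau_s`` seconds.

    Discrete-sum implementation over the overlapping support, normalized by
    the full-signal energy (no per-lag re-normalization). ``rho(0) == 1``
    exactly; a zero-energy signal yields NaN with a warning.
    """
    x = np.asarray(s, dtype=float).ravel()
    lag = int(round(tau_s * fs))
    if abs(lag) >= x.size:
        raise ParameterError(f"|tau| = {abs(tau_s)} s is not shorter than the record")
    energy = float(np.dot(x, x))
    if energy == 0:
        warnings.warn("zero-energy signal: autocorrelation undefined", stacklevel=2)
        return float("nan")
    k = abs(lag)
    num = float(np.dot(x[: x.size - k], x[k:]))
    return num / energy


def cross_correlation(s1: np.ndarray, s2: np.ndarray) -> float:
    """Mean-centred normalized cross-correlation coefficient in [-1, 1].

    Offsets are removed by centring, so the value is invariant to positive
    affine transforms of either signal and flips sign under negative scaling.
    Constant inputs have a zero denominator: NaN with a warning.
    """
    x = np.asarray(s1, dtype=float).ravel()
    y = np.asarray(s2, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ParameterError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc)) * np.sqrt(np.dot(yc, yc))
    if denom == 0:
        warnings.warn("constant signal: cross-correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


@dataclass
class StageSeries:
    """Per-stage summaries over an ordered, non-overlapping stage partition."""

    stages: list[tuple[float, float]]
    values: list

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.stages, self.stages[1:]):
            if not (a0 < a1 <= b0 < b1):
                raise ParameterError("stages must be ordered and non-overlapping")


def _stage_bounds(span: tuple[float, float], n_stages: int) -> list[tuple[float, float]]:
    t0, t1 = span
    if not t0 < t1:
        raise ParameterError(f"empty seizure span {span}")
    if n_stages < 1:
        raise ParameterError("n_stages must be >= 1")
    edges = np.linspace(t0, t1, n_stages + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def _stage_slice(n: int, fs: float, t0: float, t1: float) -> slice:
    i0 = int(round(t0 * fs))
    i1 = min(int(round(t1 * fs)), n)
    if i1 - i0 < 2:
        raise ParameterError(f"stage [{t0}, {t1}) shorter than 2 samples")
    return slice(i0, i1)


def staged_cross_correlation(
    s1: np.ndarray,
    s2: np.ndarray,
    fs: float,
    seizure_span: tuple[float, float],
    n_stages: int = 3,
) -> StageSeries:
    """Cross-correlation of a lead pair per seizure stage (equal splits)."""
    x = np.asarray(s1, dtype=float).ravel()
    y = np.asarray(s2, dtype=float).ravel()
    stages = _stage_bounds(seizure_span, n_stages)
    values = []
    for t0, t1 in stages:
        sl = _stage_slice(x.size, fs, t0, t1)
        values.append(cross_correlation(x[sl], y[sl]))
    return StageSeries(stages=stages, values=values)


def instantaneous_phase(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase of the analytic signal, radians in (-pi, pi].

    The input should already be band-limited (filter to the band of interest
    first); broadband input makes the analytic phase meaningless.
    """
    x = np.asarray(s, dtype=float)
    if not np.any(x):
        raise ParameterError("zero signal has no defined phase")
    return np.angle(sps.hilbert(x, axis=axis))


def plv(phase1: np.ndarray, phase2: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor of phase diffs.

    Always in [0, 1]; 1 for fully synchronized phases (including a constant
    offset), ~N^(-1/2) for independent phases.
    """
    p1 = np.asarray(phase1, dtype=float).ravel()
    p2 = np.asarray(phase2, dtype=float).ravel()
    if p1.size != p2.size:
        raise ParameterError(f"length mismatch: {p1.size} vs {p2.size}")
    if p1.size == 0:
        raise ParameterError("empty phase series")
    return float(np.abs(np.mean(np.exp(1j * (p1 - p2)))))


@dataclass
class PLVMatrix:
    """Symmetric lead-by-lead PLV matrix for one band and window."""

    labels: list[str]
    values: np.ndarray
    band: str = ""
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ParameterError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ParameterError("PLV matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ParameterError("PLV values must lie in [0, 1]")

    def mean_offdiag(self) -> float:
        n = len(self.labels)
        if n < 2:
            return float("nan")
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


def plv_matrix(
    series: np.ndarray,
    labels: list[str],
    fs: float | None = None,
    window: tuple[float, float] | None = None,
    phases: bool = False,
    band: str = "",
    exclude: tuple[str, ...] = (),
) -> PLVMatrix:
    """Pairwise PLV over a window; diagonal exactly 1.

    ``series`` is (leads x samples); band-limited signals by default (phases
    are extracted here), or pre-computed phases with ``phases=True``. Leads in
    ``exclude`` are dropped with a note in the matrix labels.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    keep = [i for i, lab in enumerate(labels) if lab not in exclude]
    if len(keep) < 2:
        raise ParameterError("PLV matrix needs at least 2 leads")
    x = x[keep]
    used = [labels[i] for i in keep]
    if window is not None:
        if fs is None:
            raise ParameterError("fs is required with a time window")
        sl = _stage_slice(x.shape[1], fs, *window)
        x = x[:, sl]
    ph = x if phases else instantaneous_phase(x)
    phasors = np.exp(1j * ph)
    # PLV_ij = |mean_n exp(j(ph_i - ph_j))| = |(1/N) sum phasor_i conj(phasor_j)|
    gram = phasors @ phasors.conj().T / ph.shape[1]
    values = np.abs(gram)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2, 0.0, 1.0)
    return PLVMatrix(labels=used, values=values, band=band, window=window)


def staged_plv(
    series: np.ndarray,
    labels: list[str],
    fs: float,
    seizure_span: tuple[float, float],
    n_stages: int = 3,
    band: str = "",
    exclude: tuple[str, ...] = (),
) -> StageSeries:
    """Per-stage PLV matrices over a seizure span, plus mean off-diagonal.

    Each stage is one PLV window (no sub-windowing); the scalar per-stage
    summary is the mean off-diagonal PLV. ``values`` holds the matrices; use
    ``summaries(stage_series)`` or the matrices' ``mean_offdiag``.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    stages = _stage_bounds(seizure_span, n_stages)
    mats = [
        plv_matrix(x, labels, fs=fs, window=st, band=band, exclude=exclude)
        for st in stages
    ]
    return StageSeries(stages=stages, values=mats)


def stage_summaries(stage_series: StageSeries) -> list[float]:
    """Scalar per-stage summary: mean off-diagonal PLV (or the value itself)."""
    out = []
    for v in stage_series.values:
        out.append(v.mean_offdiag() if isinstance(v, PLVMatrix) else float(v))
    return out
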