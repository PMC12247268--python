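"""Band decomposition: the slow-varying DC (Sv DC) field and the LF/HF bands.

The Sv DC component is defined by a zero-phase second-order Butterworth
low-pass at 0.5 Hz, i.e. the 0.01-0.5 Hz content of the preprocessed signal.
An equivalent time-domain definition — the per-2-second piecewise mean — is
provided as :func:`piecewise_dc`; on slow-dominated signals the two agree to
high correlation. The low-frequency (0.5-40 Hz) and high-frequency
(40-300 Hz) bands are 4th-order zero-phase Butterworth band-passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError
from .io import Recording
from .preprocess import zero_phase_sos

__all__ = [
    "SVDC_BAND",
    "LF_BAND",
    "HF_BAND",
    "BandSet",
    "extract_svdc",
    "extract_band",
    "piecewise_dc",
    "decompose",
]

SVDC_BAND = (0.01, 0.5)
LF_BAND = (0.5, 40.0)
HF_BAND = (40.0, 300.0)


@dataclass
class BandSet:
    """Per-lead Sv DC / LF / HF component series of one recording."""

    svdc: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    source_fs: float
    labels: list[str]
    band_edges: dict = field(
        default_factory=lambda: {"svdc": SVDC_BAND, "lf": LF_BAND, "hf": HF_BAND}
    )

    def __post_init__(self) -> None:
        shapes = {self.svdc.shape, self.lf.shape, self.hf.shape}
        if len(shapes) != 1:
            raise ParameterError(f"band arrays have differing shapes: {shapes}")
        for name, (lo, hi) in self.band_edges.items():
            if not lo < hi:
                raise ParameterError(f"band {name}: edges {lo}, {hi} not increasing")

    def band(self, name: str) -> np.ndarray:
        return {"svdc": self.svdc, "lf": self.lf, "hf": self.hf}[name]


def _as_array_fs(x, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(x, Recording):
        return x.data, x.fs
    if fs is None:
        raise ParameterError("fs is required when passing a bare array")
    return np.atleast_2d(np.asarray(x, dtype=float)), fs


def extract_svdc(
    rec, fs: float | None = None, cutoff_hz: float = 0.5, order: int = 2
) -> np.ndarray:
    """Isolate the Sv DC component (per-lead series).

    Zero-phase second-order Butterworth low-pass, 0.5 Hz cutoff; unity gain at
    DC and strong attenuation of everything above the cutoff. Emits a warning
    (not an error) for records shorter than ``10 / cutoff_hz`` seconds, where
    edge effects dominate.
    """
    x, fs = _as_array_fs(rec, fs)
    if fs <= 1.0:
        raise ParameterError(f"sampling rate must exceed 1 Hz, got {fs}")
    if x.shape[-1] / fs < 10.0 / cutoff_hz:
        warnings.warn(
            f"record shorter than {10.0 / cutoff_hz:.0f} s: Sv DC filter edge "
            "effects may dominate",
            stacklevel=2,
        )
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return zero_phase_sos(sos, x, pad_s=10.0 / cutoff_hz, fs=fs)


def extract_band(
    rec, low_hz: float, high_hz: float, order: int = 4, fs: float | None = None
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (per-lead series)."""
    x, fs = _as_array_fs(rec, fs)
    if not (0 < low_hz < high_hz):
        raise ParameterError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= fs / 2:
        raise ParameterError(f"high cutoff {high_hz} Hz at/above Nyquist ({fs / 2})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return zero_phase_sos(sos, x, pad_s=3.0 / low_hz, fs=fs)


def piecewise_dc(rec, fs: float | None = None, window_s: float = 2.0) -> np.ndarray:
    """Piecewise-constant DC: mean over consecutive non-overlapping windows.

    Windows are anchored at t = 0; a final partial window uses the partial
    mean. The output is a stair-step series of the same length as the input —
    on slow-dominated records it tracks :func:`extract_svdc` closely.
    """
    x, fs = _as_array_fs(rec, fs)
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    n = x.shape[-1]
    w = max(1, int(round(window_s * fs)))
    if n < w:
        raise ParameterError(f"record ({n} samples) shorter than window ({w})")
    edges = np.arange(0, n, w)
    counts = np.diff(np.append(edges, n))
    sums = np.add.reduceat(x, edges, axis=-1)
    means = sums / counts
    return np.repeat(means, counts, axis=-1)


def decompose(rec: Recording) -> BandSet:
    """Assemble the three-band decomposition of a preprocessed recording."""
    return BandSet(
        svdc=extract_svdc(rec),
        lf=extract_band(rec, *LF_BAND),
        hf=extract_band(rec, *HF_BAND),
        source_fs=rec.fs,
        labels=list(rec.labels),
    )
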