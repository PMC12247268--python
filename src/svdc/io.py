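"""Recording container, SEEG lead labels, and file I/O.

Recordings are multichannel time series in microvolts with a single sampling
rate. Two on-disk formats are supported: European Data Format (EDF/EDF+, via
the minimal reader/writer in :mod:`svdc._edf`) and delimited text (CSV, one
column per channel, optional header row, with a tab-separated sidecar file for
annotations).

Time convention: seconds from the start of the recording, 0-based; windows are
half-open ``[t0, t1)`` and sample ``i`` covers ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    ParameterError,
    ParseError,
    UnsupportedFormatError,
)

__all__ = [
    "Annotation",
    "Recording",
    "LeadLabel",
    "parse_lead_label",
    "read_edf",
    "read_delimited",
    "write_recording",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class Annotation:
    """A timed text mark (e.g. a seizure onset)."""

    onset: float
    duration: float
    text: str


@dataclass
class Recording:
    """Multichannel recording in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, float64, microvolts.
    fs
        Sampling rate in Hz, identical for every channel.
    labels
        Ordered, unique channel labels (SEEG convention: electrode letter +
        contact number, e.g. ``"A3"``).
    start_time
        Offset of sample 0 in seconds (0 for most uses).
    annotations
        Timed text marks, e.g. seizure onsets.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    start_time: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        dupes = {l for l in self.labels if self.labels.count(l) > 1}
        if dupes:
            raise FormatError(f"duplicate channel labels: {sorted(dupes)}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("sample values must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def sample_slice(self, t0: float, t1: float) -> tuple[int, int]:
        """Sample index range covering the half-open window ``[t0, t1)``."""
        if t1 <= t0:
            raise ParameterError(f"empty window [{t0}, {t1})")
        eps = 1e-9
        i0 = int(np.ceil(t0 * self.fs - eps))
        i1 = int(np.ceil(t1 * self.fs - eps))
        return max(i0, 0), min(i1, self.n_samples)

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with replaced samples (same metadata)."""
        return Recording(
            np.asarray(data, dtype=float),
            self.fs,
            list(self.labels),
            self.start_time,
            list(self.annotations),
        )

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


_LEAD_RE = re.compile(r"^([A-Za-z]+)\s*'?\s*(\d+)$")


@dataclass(frozen=True, order=True)
class LeadLabel:
    """SEEG lead label: electrode letter(s) plus 1-based contact number."""

    electrode: str
    contact: int

    def __post_init__(self) -> None:
        if self.contact < 1:
            raise ParseError(f"contact must be >= 1, got {self.contact}")

    def __str__(self) -> str:
        return f"{self.electrode}{self.contact}"


def parse_lead_label(text: str) -> LeadLabel:
    """Parse a label like ``"A3"`` into ``LeadLabel("A", 3)``.

    Raises :class:`ParseError` when the text is not letters followed by digits.
    """
    m = _LEAD_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse lead label {text!r}")
    return LeadLabel(m.group(1), int(m.group(2)))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (units converted to uV)."""
    from . import _edf

    return _edf.read_edf(path)


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annotations.tsv")


def read_delimited(path, fs: float, labels: list[str] | None = None) -> Recording:
    """Read a comma-separated numeric table, one column per channel.

    A single non-numeric first row is used as channel labels when the
    ``labels`` argument is not given. Any other non-numeric cell raises
    :class:`ParseError` with its row index; ragged rows raise
    :class:`FormatError`. A sidecar ``<path>.annotations.tsv`` file, when
    present, is loaded as annotations.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    try:
        raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed delimited table: {exc}") from exc

    header = None
    first = raw.iloc[0]
    if not first.map(_is_number).all():
        header = [str(v).strip() for v in first]
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.empty:
        raise FormatError(f"{path}: no data rows")

    values = np.empty((len(raw), raw.shape[1]), dtype=float)
    for j in range(raw.shape[1]):
        cells = raw.iloc[:, j].to_numpy()
        try:
            col = cells.astype(np.float64)  # exact strtod, unlike to_numeric
        except (TypeError, ValueError):
            col = np.array(
                [float(c) if _is_number(c) else np.nan for c in cells]
            )
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            row = int(bad[0]) + (1 if header is not None else 0)
            raise ParseError(
                f"{path}: non-finite or non-numeric value in row {row}, column {j}"
            )
        values[:, j] = col

    if labels is None:
        labels = header if header is not None else [f"ch{j}" for j in range(values.shape[1])]
    annotations = []
    if _sidecar(path).exists():
        annotations = read_annotations(_sidecar(path))
    return Recording(values.T, fs=fs, labels=list(labels), annotations=annotations)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_annotations(path) -> list[Annotation]:
    """Read a tab-separated (onset_s, duration_s, label) annotation file."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {i}: expected 3 tab-separated fields")
        try:
            out.append(Annotation(float(parts[0]), float(parts[1]), parts[2]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


def write_annotations(annotations: list[Annotation], path) -> Path:
    path = Path(path)
    lines = [f"{a.onset:.6f}\t{a.duration:.6f}\t{a.text}" for a in annotations]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_recording(rec: Recording, path, format: str = "edf") -> Path:
    """Write a recording as ``edf`` or ``delimited`` text.

    The matching reader round-trips fs, labels and annotations exactly, and
    samples exactly (delimited) or within 16-bit quantization (EDF).
    """
    path = Path(path)
    if format == "edf":
        from . import _edf

        _edf.write_edf(rec, path)
    elif format == "delimited":
        df = pd.DataFrame(rec.data.T, columns=rec.labels)
        df.to_csv(path, index=False, float_format="%.17g")
        if rec.annotations:
            write_annotations(rec.annotations, _sidecar(path))
    else:
        raise UnsupportedFormatError(f"unknown recording format {format!r}")
    return path
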