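"""Minimal EDF/EDF+C reader and writer.

Supports the subset of the format this package needs: one uniform sampling
rate across ordinary signals, 16-bit samples, physical units of uV/mV/V, and a
single ``EDF Annotations`` signal carrying time-stamped annotation lists
(TALs). Signals are written with 1-second data records; a recording whose
length is not a whole number of seconds is zero-padded to the next record
boundary (with a warning).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedFormatError

_ANN_LABEL = "EDF Annotations"
_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


def _fix(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_num(x: float, width: int = 8) -> bytes:
    """Format a number into a fixed-width EDF ASCII field."""
    if float(x) == int(x) and abs(x) < 10 ** (width - 1):
        s = str(int(x))
    else:
        for prec in range(width - 2, -1, -1):
            s = f"{x:.{prec}g}"
            if len(s) <= width and "e" not in s and "E" not in s:
                break
        else:
            raise FormatError(f"cannot format {x} into {width} chars")
    return _fix(s, width)


def write_edf(rec, path) -> Path:
    """Write a Recording as EDF+C with an annotations signal."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedFormatError(
            f"EDF writer requires an integer sampling rate, got {fs}"
        )
    fs = int(round(fs))
    spr = fs  # samples per record, record duration 1 s
    n_records = math.ceil(rec.n_samples / spr)
    if n_records * spr != rec.n_samples:
        warnings.warn(
            "recording length is not a whole number of seconds; the final EDF "
            "record is zero-padded",
            stacklevel=2,
        )

    # TALs: every record starts with a timestamp TAL; user annotations are
    # appended to the record containing their onset.
    tals: list[list[bytes]] = []
    for r in range(n_records):
        tals.append([f"+{r}\x14\x14\x00".encode("ascii")])
    for a in rec.annotations:
        r = min(int(a.onset), n_records - 1) if n_records else 0
        onset = f"{a.onset:.6f}".rstrip("0").rstrip(".")
        dur = f"{a.duration:.6f}".rstrip("0").rstrip(".")
        tal = f"+{onset}\x15{dur}\x14{a.text}\x14\x00".encode("utf-8")
        tals[r].append(tal)
    ann_bytes = max(sum(len(t) for t in rec_tals) for rec_tals in tals) if tals else 16
    ann_spr = max(8, (ann_bytes + 1) // 2)  # int16 samples reserved per record

    n_sig = rec.n_channels + 1
    pmins, pmaxs, gains = [], [], []
    for ch in rec.data:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        # widen, then round outward to short decimal fields
        span = hi - lo
        lo, hi = lo - 0.001 * span, hi + 0.001 * span
        lo = float(_fmt_num(math.floor(lo * 100) / 100).decode())
        hi = float(_fmt_num(math.ceil(hi * 100) / 100).decode())
        pmins.append(lo)
        pmaxs.append(hi)
        gains.append((hi - lo) / 65535.0)

    header = bytearray()
    header += _fix("0", 8)
    header += _fix("X X X X", 80)  # local patient id
    header += _fix("Startdate X X X X", 80)  # local recording id
    header += _fix("01.01.00", 8)
    header += _fix("00.00.00", 8)
    header += _fmt_num(256 * (1 + n_sig), 8)
    header += _fix("EDF+C", 44)
    header += _fmt_num(n_records, 8)
    header += _fmt_num(1, 8)  # record duration s
    header += _fix(str(n_sig), 4)

    labels = list(rec.labels) + [_ANN_LABEL]
    dims = ["uV"] * rec.n_channels + [""]
    pmin_all = pmins + [-1.0]
    pmax_all = pmaxs + [1.0]
    dmin_all = [-32768] * rec.n_channels + [-32768]
    dmax_all = [32767] * rec.n_channels + [32767]
    spr_all = [spr] * rec.n_channels + [ann_spr]

    for lab in labels:
        header += _fix(lab, 16)
    for _ in labels:
        header += _fix("", 80)  # transducer
    for d in dims:
        header += _fix(d, 8)
    for v in pmin_all:
        header += _fmt_num(v, 8)
    for v in pmax_all:
        header += _fmt_num(v, 8)
    for v in dmin_all:
        header += _fmt_num(v, 8)
    for v in dmax_all:
        header += _fmt_num(v, 8)
    for _ in labels:
        header += _fix("", 80)  # prefiltering
    for v in spr_all:
        header += _fmt_num(v, 8)
    for _ in labels:
        header += _fix("", 32)

    padded = np.zeros((rec.n_channels, n_records * spr))
    padded[:, : rec.n_samples] = rec.data
    digital = np.empty_like(padded, dtype=np.int16)
    for i in range(rec.n_channels):
        d = np.round((padded[i] - pmins[i]) / gains[i]) + dmin_all[i]
        digital[i] = np.clip(d, -32768, 32767).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for i in range(rec.n_channels):
                fh.write(digital[i, r * spr : (r + 1) * spr].tobytes())
            ann = b"".join(tals[r])
            ann = ann + b"\x00" * (2 * ann_spr - len(ann))
            fh.write(ann)
    return path


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", "replace").strip()


def read_edf(path):
    """Read an EDF/EDF+ file into a Recording (physical units scaled to uV)."""
    from .io import Annotation, Recording

    path = Path(path)
    size = path.stat().st_size
    if size < 256:
        raise FormatError(f"{path}: too small to hold an EDF header ({size} bytes)")
    with open(path, "rb") as fh:
        fh.read(8)  # version
        fh.read(160)  # patient + recording ids
        fh.read(16)  # date + time
        try:
            header_bytes = int(_read_field(fh, 8))
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF header") from exc
        fh.read(44)  # reserved
        try:
            n_records = int(_read_field(fh, 8))
            record_dur = float(_read_field(fh, 8))
            n_sig = int(_read_field(fh, 4))
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF header") from exc
        if n_sig < 1 or record_dur <= 0 or n_records < 0:
            raise FormatError(f"{path}: implausible EDF header")
        if size < header_bytes:
            raise FormatError(f"{path}: truncated header")

        labels = [_read_field(fh, 16) for _ in range(n_sig)]
        fh.read(80 * n_sig)  # transducer
        dims = [_read_field(fh, 8) for _ in range(n_sig)]
        pmins = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        pmaxs = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        dmins = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        dmaxs = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        fh.read(80 * n_sig)  # prefiltering
        sprs = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        fh.read(32 * n_sig)
        fh.seek(header_bytes)
        payload = fh.read()

    is_ann = [lab == _ANN_LABEL for lab in labels]
    sig_idx = [i for i in range(n_sig) if not is_ann[i]]
    if not sig_idx:
        raise FormatError(f"{path}: no ordinary signals")
    ord_sprs = {sprs[i] for i in sig_idx}
    if len(ord_sprs) > 1:
        raise UnsupportedFormatError(
            f"{path}: mixed per-channel sampling rates {sorted(ord_sprs)} "
            "are not supported"
        )
    spr = ord_sprs.pop()
    fs = spr / record_dur
    ord_labels = [labels[i] for i in sig_idx]
    dupes = {l for l in ord_labels if ord_labels.count(l) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate channel labels: {sorted(dupes)}")

    rec_len = 2 * sum(sprs)
    if n_records * rec_len > len(payload):
        n_records = len(payload) // rec_len
    data = np.zeros((len(sig_idx), n_records * spr))
    ann_blobs: list[bytes] = []
    offsets = np.cumsum([0] + [2 * s for s in sprs])
    for r in range(n_records):
        base = r * rec_len
        for k, i in enumerate(sig_idx):
            raw = payload[base + offsets[i] : base + offsets[i] + 2 * sprs[i]]
            data[k, r * spr : (r + 1) * spr] = np.frombuffer(raw, dtype="<i2")
        for i in range(n_sig):
            if is_ann[i]:
                ann_blobs.append(payload[base + offsets[i] : base + offsets[i + 1]])

    for k, i in enumerate(sig_idx):
        if dmaxs[i] == dmins[i] or pmaxs[i] == pmins[i]:
            raise FormatError(f"{path}: degenerate scaling for signal {labels[i]!r}")
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        scale = _UNIT_TO_UV.get(dims[i].lower(), 1.0)
        data[k] = ((data[k] - dmins[i]) * gain + pmins[i]) * scale

    annotations = [
        Annotation(on, du, tx) for on, du, tx in _parse_tals(b"".join(ann_blobs))
    ]
    return Recording(data, fs=fs, labels=ord_labels, annotations=annotations)


def _parse_tals(blob: bytes):
    """Yield (onset, duration, text) from concatenated TAL bytes."""
    for chunk in blob.split(b"\x00"):
        if not chunk:
            continue
        head, *texts = chunk.split(b"\x14")
        texts = [t for t in texts if t]
        if not texts:
            continue  # record timestamp TAL
        if b"\x15" in head:
            onset_b, dur_b = head.split(b"\x15", 1)
            duration = float(dur_b)
        else:
            onset_b, duration = head, 0.0
        onset = float(onset_b)
        for t in texts:
            yield onset, duration, t.decode("utf-8", "replace")
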