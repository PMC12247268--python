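import numpy as np
import pytest

from svdc import Recording

FS = 1024.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tone(freq_hz: float, dur_s: float, fs: float = FS, amp: float = 1.0,
              phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * fs))) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


def tone_recording(freq_hz, dur_s, fs=FS, amp=1.0, n_channels=1, labels=None):
    x = make_tone(freq_hz, dur_s, fs, amp)
    data = np.tile(x, (n_channels, 1))
    labels = labels or [f"A{i + 1}" for i in range(n_channels)]
    return Recording(data, fs=fs, labels=labels)


def interior_rms(x: np.ndarray, frac: float = 0.25) -> float:
    """RMS over the interior of a signal, away from filter edges."""
    n = x.shape[-1]
    lo, hi = int(n * frac), int(n * (1 - frac))
    return float(np.sqrt(np.mean(np.square(x[..., lo:hi]))))


def interval_jaccard(a, b) -> float:
    """Jaccard index of two interval unions (exact, no sampling)."""

    def total(ivs):
        return sum(t1 - t0 for t0, t1 in ivs)

    inter = 0.0
    for a0, a1 in a:
        for b0, b1 in b:
            inter += max(0.0, min(a1, b1) - max(a0, b0))
    union = total(a) + total(b) - inter
    return inter / union if union > 0 else 1.0
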