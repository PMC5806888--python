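"""Raw 1 kHz EOG -> 2-dimensional *baseform* feature streams.

Two canonical paths exist.  The continuous path removes baseline drift with
a first-order DC blocker ``H(z) = (1 - z^-1) / (1 - R z^-1)`` (R = 0.999),
low-passes at 20 Hz with a linear-phase FIR applied at zero phase, and
decimates 1 kHz -> 50 Hz.  The isolated path median-smooths the raw signal
and decimates 1 kHz -> 125 Hz, following the isolated eye-writing baseline
convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import EOGRecording

__all__ = [
    "BaseformSequence",
    "dc_block",
    "fir_lowpass",
    "median_smooth",
    "decimate",
    "make_baseform",
]


@dataclass
class BaseformSequence:
    """Filtered, downsampled (horizontal, vertical) frame sequence."""

    frames: np.ndarray  # (n, 2)
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 2:
            raise ValueError("baseform frames must be (n, 2)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.frames)


def dc_block(x, R: float = 0.999) -> np.ndarray:
    """First-order DC blocker ``y[n] = x[n] - x[n-1] + R*y[n-1]``.

    Zero gain at DC, unity gain in the passband; R controls how sharp the
    high-pass corner is (0.999 at 1 kHz puts it well below eye-movement
    frequencies).
    """
    if not (0.0 < R < 1.0):
        raise ValueError(f"R must lie in (0, 1), got {R}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return signal.lfilter([1.0, -1.0], [1.0, -R], x)


def fir_lowpass(x, cutoff_hz: float = 20.0, rate_hz: float = 1000.0,
                num_taps: int = 201) -> np.ndarray:
    """Zero-phase linear-phase FIR low-pass (windowed-sinc, Hamming window).

    The symmetric filter is applied once and the group delay of
    ``(num_taps - 1) / 2`` samples is compensated by edge-replicated
    padding, so the output has the same length and no lag.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not (0.0 < cutoff_hz < rate_hz / 2.0):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2})")
    if num_taps % 2 == 0:
        raise ValueError("num_taps must be odd for an integer group delay")
    taps = signal.firwin(num_taps, cutoff_hz, fs=rate_hz, window="hamming")
    half = (num_taps - 1) // 2
    padded = np.pad(x, half, mode="edge")
    return np.convolve(padded, taps, mode="valid")


def median_smooth(x, window: int = 9) -> np.ndarray:
    """Sliding median with reflected edges; rejects impulsive spikes."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    return ndimage.median_filter(x, size=window, mode="reflect")


def decimate(x, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0.

    Anti-aliasing is the caller's responsibility (the 20 Hz low-pass covers
    the 1 kHz -> 50 Hz step).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    x = np.asarray(x)
    return x[:: int(factor)].copy()


def make_baseform(rec: EOGRecording, path: str = "continuous", *,
                  R: float = 0.999, cutoff_hz: float = 20.0, num_taps: int = 201,
                  median_window: int = 9, target_rate_hz: float | None = None
                  ) -> BaseformSequence:
    """Run one of the two canonical preprocessing paths on a recording.

    ``continuous``: DC blocker -> 20 Hz FIR low-pass -> decimate to 50 Hz.
    ``isolated``:   median smoothing -> decimate to 125 Hz.
    """
    if path not in ("continuous", "isolated"):
        raise ValueError(f"unknown preprocessing path {path!r}")
    if target_rate_hz is None:
        target_rate_hz = 50.0 if path == "continuous" else 125.0
    ratio = rec.sample_rate_hz / target_rate_hz
    factor = max(1, int(round(ratio)))
    if not math.isclose(ratio, factor):
        warnings.warn(
            f"rate {rec.sample_rate_hz} not divisible by target {target_rate_hz}; "
            f"using nearest integer factor {factor}"
        )
    chans = []
    for chan in (rec.horizontal, rec.vertical):
        if path == "continuous":
            y = dc_block(chan, R=R)
            y = fir_lowpass(y, cutoff_hz=cutoff_hz, rate_hz=rec.sample_rate_hz,
                            num_taps=num_taps)
        else:
            y = median_smooth(chan, window=median_window)
        chans.append(decimate(y, factor))
    frames = np.stack(chans, axis=1)
    return BaseformSequence(frames=frames, frame_rate_hz=rec.sample_rate_hz / factor)
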