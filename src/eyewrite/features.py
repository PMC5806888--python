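"""Expanded feature construction and the neural front-end.

The continuous pipeline takes the 2-dim baseform stream through:
deltas/delta-deltas (2 -> 6 dims, same rate), pairwise frame joining
(6 -> 12 dims, half rate), and — for the hybrid network only — temporal
splicing with +-5 frames of context (12 -> 132 dims) followed by a PCA
rotation that decorrelates the spliced dimensions without discarding any.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureSequence",
    "Decorrelator",
    "append_deltas",
    "join_pairs",
    "splice",
    "fit_decorrelator",
    "apply_decorrelator",
]


@dataclass
class FeatureSequence:
    """Uniform-dimension frame sequence with its frame rate."""

    frames: np.ndarray  # (n, d)
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D array (n, d)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def dim(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return len(self.frames)


def _delta(frames: np.ndarray, window: int) -> np.ndarray:
    """HTK-style regression delta with edge replication.

    d_t = sum_{w=1..W} w * (c_{t+w} - c_{t-w}) / (2 * sum_{w} w^2)
    """
    n = len(frames)
    denom = 2.0 * sum(w * w for w in range(1, window + 1))
    out = np.zeros_like(frames)
    for w in range(1, window + 1):
        plus = frames[np.minimum(np.arange(n) + w, n - 1)]
        minus = frames[np.maximum(np.arange(n) - w, 0)]
        out += w * (plus - minus)
    return out / denom


def append_deltas(fs: FeatureSequence, window: int = 2) -> FeatureSequence:
    """Append speed (delta) and acceleration (delta-delta) components."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(fs) < window + 1:
        raise ValueError(f"need at least {window + 1} frames, got {len(fs)}")
    d = _delta(fs.frames, window)
    dd = _delta(d, window)
    return FeatureSequence(np.concatenate([fs.frames, d, dd], axis=1), fs.frame_rate_hz)


def join_pairs(fs: FeatureSequence) -> FeatureSequence:
    """Concatenate non-overlapping consecutive frame pairs; halves the rate.

    A trailing odd frame is dropped.
    """
    n = len(fs)
    if n < 2:
        raise ValueError("need at least 2 frames to join pairs")
    m = n // 2
    paired = fs.frames[: 2 * m].reshape(m, 2 * fs.dim)
    return FeatureSequence(paired, fs.frame_rate_hz / 2.0)


def splice(fs: FeatureSequence, context: int = 5) -> FeatureSequence:
    """Attach ``context`` preceding and succeeding frames to every frame.

    Edge frames replicate the boundary frame; frame count and rate are
    unchanged, dimensionality becomes ``d * (2*context + 1)``.
    """
    if context < 0:
        raise ValueError("context must be >= 0")
    if context == 0:
        return FeatureSequence(fs.frames.copy(), fs.frame_rate_hz)
    n = len(fs)
    idx = np.arange(n)
    blocks = [fs.frames[np.clip(idx + off, 0, n - 1)]
              for off in range(-context, context + 1)]
    return FeatureSequence(np.concatenate(blocks, axis=1), fs.frame_rate_hz)


@dataclass
class Decorrelator:
    """Mean-centering plus orthonormal PCA rotation.

    ``scale`` is an optional per-component divisor applied after rotation
    (unit-variance whitening when enabled at fit time); with ``scale`` None
    the transform is a pure rotation and fully invertible.
    """

    mean: np.ndarray
    rotation: np.ndarray  # (d, d), columns are principal axes
    scale: np.ndarray | None = None
    fitted_on: str = field(default="")

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        d = self.rotation.shape[0]
        if self.rotation.shape != (d, d) or self.mean.shape != (d,):
            raise ValueError("inconsistent decorrelator shapes")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(d)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)
            if self.scale.shape != (d,) or np.any(self.scale <= 0):
                raise ValueError("scale must be d positive values")


def fit_decorrelator(data: np.ndarray, *, eps: float = 1e-10,
                     whiten: bool = False) -> Decorrelator:
    """Fit a PCA rotation on a (n, d) matrix of (spliced) frames.

    Rank-deficient data is regularised by ``eps`` on the covariance
    diagonal; all dimensions are kept.  ``whiten`` additionally rescales
    each component to unit variance (used by the neural front-end, whose
    optimizer expects inputs of order 1; the default keeps the pure
    rotation).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("fitting data must be (n, d)")
    n, d = data.shape
    if n < d:
        raise ValueError(f"need at least d={d} frames to fit, got {n}")
    mean = data.mean(axis=0)
    cov = np.cov(data - mean, rowvar=False)
    cov = np.atleast_2d(cov) + eps * np.eye(d)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]  # descending variance
    scale = None
    if whiten:
        ev = eigval[order]
        scale = np.sqrt(np.maximum(ev, 1e-8 * ev.max()))
    return Decorrelator(mean=mean, rotation=eigvec[:, order], scale=scale,
                        fitted_on=f"n={n},d={d}")


def apply_decorrelator(dec: Decorrelator, fs: FeatureSequence) -> FeatureSequence:
    if fs.dim != dec.mean.shape[0]:
        raise ValueError(f"dimension mismatch: {fs.dim} vs {dec.mean.shape[0]}")
    out = (fs.frames - dec.mean) @ dec.rotation
    if dec.scale is not None:
        out = out / dec.scale
    return FeatureSequence(out, fs.frame_rate_hz)
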