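"""Isolated-stroke baseline: dynamic time warping template matching.

Each stroke class is represented by one or more templates; a query is
classified by the nearest template under the unconstrained (full-search)
DTW cost with Euclidean local distances and the symmetric step pattern
{(i+1,j), (i,j+1), (i+1,j+1)}.  A nine-point gain calibration maps raw
microvolt amplitudes to normalized gaze displacement, compensating
electrode-placement distortions, as in isolated eye-writing systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EOGRecording

__all__ = [
    "Template",
    "GainCalibration",
    "dtw_distance",
    "classify_stroke",
    "fit_calibration",
    "apply_calibration",
]


@dataclass
class Template:
    stroke_id: int
    frames: np.ndarray
    source_user: str = ""

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if len(self.frames) == 0:
            raise ValueError("empty template")


def dtw_distance(X, Y, *, return_alignment: bool = True):
    """Minimal-cost DTW alignment of two vector sequences.

    Endpoints anchored, no band constraint, unit step weights.  Returns
    ``(cost, alignment)`` where alignment is a list of (i, j) index pairs
    of length L with max(M, N) <= L < M + N.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("empty sequence")
    M, N = len(X), len(Y)
    # local Euclidean distances
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    local = np.sqrt(np.maximum(d2, 0.0))
    D = np.full((M, N), np.inf)
    D[0, :] = np.cumsum(local[0, :])
    D[:, 0] = np.cumsum(local[:, 0])
    for i in range(1, M):
        for j in range(1, N):
            D[i, j] = local[i, j] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    cost = float(D[-1, -1])
    if not return_alignment:
        return cost, None
    # backtrace, preferring the diagonal on ties
    path = [(M - 1, N - 1)]
    i, j = M - 1, N - 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            choices = ((D[i - 1, j - 1], i - 1, j - 1),
                       (D[i - 1, j], i - 1, j),
                       (D[i, j - 1], i, j - 1))
            _, i, j = min(choices, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return cost, path


def classify_stroke(templates, X) -> int:
    """Nearest-template classification; ties go to the lower stroke id."""
    templates = list(templates)
    if not templates:
        raise ValueError("no templates")
    best = None
    for t in templates:
        cost, _ = dtw_distance(t.frames, X, return_alignment=False)
        if best is None or cost < best[0] or (cost == best[0] and t.stroke_id < best[1]):
            best = (cost, t.stroke_id)
    return best[1]


@dataclass
class GainCalibration:
    """Per-channel affine map from microvolts to gaze displacement units."""

    h_gain: float
    h_offset: float
    v_gain: float
    v_offset: float

    def __post_init__(self) -> None:
        if self.h_gain == 0 or self.v_gain == 0:
            raise ValueError("calibration gains must be nonzero")


def fit_calibration(plateau_uv, targets) -> GainCalibration:
    """Least-squares per-channel affine fit of plateau amplitude vs angle.

    ``plateau_uv`` is an (n, 2) array of mean EOG amplitudes measured while
    fixating n known gaze targets; ``targets`` is the matching (n, 2) array
    of normalized displacements (the classic layout is a 3x3 grid of nine
    positions).  Rank-deficient target layouts (e.g. all targets on one
    axis) are rejected per channel.
    """
    plateau_uv = np.atleast_2d(np.asarray(plateau_uv, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if plateau_uv.shape != targets.shape or plateau_uv.shape[1] != 2:
        raise ValueError("plateau and target arrays must both be (n, 2)")
    gains = []
    for ch in range(2):
        t = targets[:, ch]
        if np.ptp(t) <= 0:
            raise np.linalg.LinAlgError(
                f"channel {('horizontal', 'vertical')[ch]}: calibration targets "
                "are rank-deficient (no spread on this axis)")
        A = np.stack([t, np.ones_like(t)], axis=1)
        coef, *_ = np.linalg.lstsq(A, plateau_uv[:, ch], rcond=None)
        gains.append(coef)  # (gain uV per unit, offset uV)
    (hg, ho), (vg, vo) = gains
    return GainCalibration(h_gain=float(hg), h_offset=float(ho),
                           v_gain=float(vg), v_offset=float(vo))


def apply_calibration(cal: GainCalibration, rec: EOGRecording) -> EOGRecording:
    """Return a recording normalized to unit gaze gain."""
    return EOGRecording(
        sample_rate_hz=rec.sample_rate_hz,
        horizontal=(rec.horizontal - cal.h_offset) / cal.h_gain,
        vertical=(rec.vertical - cal.v_offset) / cal.v_gain,
        meta={**rec.meta, "calibrated": "true"},
    )
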