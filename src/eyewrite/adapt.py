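"""GMM-HMM user adaptation: global MLLR mean transform and MAP mean update.

Both methods move only the Gaussian means; variances, weights and
transitions stay frozen.  Statistics come from forward-backward posteriors
of the user-independent model against the adaptation data's compiled
motion sequences (embedded supervision, alignments latent).  MLLR fits a
single global affine transform ``mu' = A mu + b`` — few free parameters,
so it works from minutes of data; MAP interpolates each observed mean
toward its empirical estimate with prior weight tau and approaches the
maximum-likelihood update as data grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hmm import ModelSet, SuffStats, accumulate_stats

logger = logging.getLogger(__name__)

__all__ = [
    "AdaptationStats",
    "MLLRTransform",
    "InsufficientOccupancyError",
    "accumulate_adaptation_stats",
    "mllr_update",
    "map_update",
]


class InsufficientOccupancyError(ValueError):
    """Too little adaptation data to estimate the requested transform."""


@dataclass
class AdaptationStats:
    """Per-Gaussian occupancies and first-order sums over adaptation data."""

    occ: np.ndarray     # (E, M_max)
    sum_x: np.ndarray   # (E, M_max, d)
    loglik: float
    n_frames: int

    @property
    def total_occupancy(self) -> float:
        return float(self.occ.sum())

    @classmethod
    def from_suffstats(cls, s: SuffStats) -> "AdaptationStats":
        return cls(occ=s.occ, sum_x=s.sum_x, loglik=s.loglik, n_frames=s.n_frames)


def accumulate_adaptation_stats(ms: ModelSet, corpus) -> AdaptationStats:
    """Forward-backward statistics of ``(features, motions)`` adaptation pairs."""
    return AdaptationStats.from_suffstats(accumulate_stats(ms, corpus))


@dataclass
class MLLRTransform:
    """Global affine mean transform ``mu' = A mu + b``."""

    A: np.ndarray  # (d, d)
    b: np.ndarray  # (d,)

    def apply(self, mu: np.ndarray) -> np.ndarray:
        return mu @ self.A.T + self.b


def estimate_mllr(ms: ModelSet, stats: AdaptationStats, *,
                  ridge: float = 1e-6) -> MLLRTransform:
    """Row-wise maximum-likelihood solution for the global transform.

    With diagonal covariances the d rows of [A b] decouple: row i solves
    ``G_i w_i = k_i`` with ``G_i = sum_g (occ_g / var_gi) xi_g xi_g^T`` and
    ``k_i = sum_g (sumx_gi / var_gi) xi_g``, where ``xi_g = [mu_g; 1]``.
    """
    d = ms.dim
    if stats.total_occupancy < d + 1:
        raise InsufficientOccupancyError(
            f"total occupancy {stats.total_occupancy:.1f} < d+1 = {d + 1}")
    G = np.zeros((d, d + 1, d + 1))
    k = np.zeros((d, d + 1))
    for e, gme in enumerate(ms.emissions):
        M = gme.n_components
        for m in range(M):
            occ = stats.occ[e, m]
            if occ <= 0:
                continue
            xi = np.append(gme.means[m], 1.0)
            outer = np.outer(xi, xi)
            inv_var = 1.0 / gme.variances[m]
            G += (occ * inv_var)[:, None, None] * outer[None, :, :]
            k += (stats.sum_x[e, m] * inv_var)[:, None] * xi[None, :]
    W = np.zeros((d, d + 1))
    for i in range(d):
        Gi = G[i]
        try:
            W[i] = np.linalg.solve(Gi, k[i])
        except np.linalg.LinAlgError:
            logger.warning("MLLR accumulator singular; ridge-regularizing")
            W[i] = np.linalg.solve(Gi + ridge * np.trace(Gi) / (d + 1) * np.eye(d + 1),
                                   k[i])
    return MLLRTransform(A=W[:, :d], b=W[:, d])


def mllr_update(ms: ModelSet, stats: AdaptationStats) -> ModelSet:
    """Apply the single-class MLLR mean transform to every Gaussian."""
    transform = estimate_mllr(ms, stats)
    new = ms.copy()
    for gme in new.emissions:
        gme.means = transform.apply(gme.means)
    new.meta["adaptation"] = "mllr"
    return new


def map_update(ms: ModelSet, stats: AdaptationStats, tau: float = 10.0) -> ModelSet:
    """MAP mean interpolation ``mu' = (tau mu0 + sum_g x) / (tau + occ)``.

    Gaussians with zero occupancy keep their prior mean.  tau -> 0 gives
    the maximum-likelihood (empirical) mean; tau -> inf keeps the prior.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    new = ms.copy()
    for e, gme in enumerate(new.emissions):
        M = gme.n_components
        occ = stats.occ[e, :M]
        seen = occ > 0
        if not np.any(seen):
            continue
        upd = (tau * gme.means + stats.sum_x[e, :M]) / (tau + occ)[:, None]
        gme.means = np.where(seen[:, None], upd, gme.means)
    new.meta["adaptation"] = f"map(tau={tau:g})"
    return new
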