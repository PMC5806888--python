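"""Unit HMMs with Gaussian-mixture state outputs.

Every basic motion unit is a 4-state left-to-right HMM (self-loop plus a
single forward arc per state), so a compiled motion sequence is one long
linear state chain: forward, backward and Viterbi passes are all O(T * S)
shift-based recursions.  Training is embedded Baum-Welch: supervision is
the motion-sequence level only, alignments stay latent.  Mixtures grow by
binary splitting; context dependence comes from tri-motion cloning
followed by decision-tree state clustering over context questions.

Emission distributions are stored in a flat table (``ModelSet.emissions``)
and referenced by index from each unit's four states.  That indirection is
what makes state tying and the hybrid neural scorer drop-in replacements:
anything that can produce a (T, n_emissions) log-likelihood matrix can
drive alignment and decoding.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSequence
from .io import LabelSegment
from .protocol import SIL

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianMixtureState",
    "UnitHMM",
    "ModelSet",
    "ContextQuestion",
    "StateTying",
    "InfeasibleAlignmentError",
    "N_STATES",
    "tri_label",
    "tri_labels_of",
    "flat_start",
    "forward_loglik",
    "viterbi_align",
    "accumulate_stats",
    "baum_welch_iteration",
    "train_baum_welch",
    "split_mixtures",
    "expand_to_trimotion",
    "default_questions",
    "collect_tying_stats",
    "cluster_states",
    "apply_tying",
    "standard_training",
]

N_STATES = 4          # emitting states per unit
LZERO = -1.0e10       # effective log(0) used in recursions


class InfeasibleAlignmentError(ValueError):
    """The feature sequence is shorter than the minimum state path."""


# ---------------------------------------------------------------------------
# emission distributions

@dataclass
class GaussianMixtureState:
    """Diagonal-covariance GMM output distribution of one (tied) state."""

    weights: np.ndarray   # (M,)
    means: np.ndarray     # (M, d)
    variances: np.ndarray  # (M, d)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_logpdf(self, X: np.ndarray) -> np.ndarray:
        """(T, M) log of weight_m * N(x_t | mu_m, var_m)."""
        X = np.atleast_2d(X)
        d = self.dim
        const = -0.5 * (d * np.log(2.0 * np.pi) + np.log(self.variances).sum(axis=1))
        diff = X[:, None, :] - self.means[None, :, :]     # (T, M, d)
        quad = -0.5 * (diff * diff / self.variances[None, :, :]).sum(axis=2)
        return np.log(np.maximum(self.weights, 1e-300))[None, :] + const[None, :] + quad

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp
        return logsumexp(self.component_logpdf(X), axis=1)


@dataclass
class UnitHMM:
    """Left-to-right unit model: 4 emission-state ids + self-loop probs."""

    name: str
    state_ids: np.ndarray       # (N_STATES,) indices into ModelSet.emissions
    stay: np.ndarray            # (N_STATES,) self-loop probabilities

    def __post_init__(self) -> None:
        self.state_ids = np.asarray(self.state_ids, dtype=int)
        self.stay = np.asarray(self.stay, dtype=float)
        if self.state_ids.shape != (N_STATES,) or self.stay.shape != (N_STATES,):
            raise ValueError(f"unit {self.name}: expected {N_STATES} states")
        if np.any((self.stay <= 0) | (self.stay >= 1)):
            raise ValueError(f"unit {self.name}: stay probabilities must be in (0,1)")


def tri_label(left, center: str, right) -> str:
    """HTK-style context-dependent label; None marks a context boundary."""
    if center == SIL:
        return SIL  # sil is context-independent
    name = center
    if left is not None:
        name = f"{left}-{name}"
    if right is not None:
        name = f"{name}+{right}"
    return name


def parse_tri(label: str):
    """Return (left, center, right) of a (possibly context-free) label."""
    left = right = None
    rest = label
    if "-" in rest:
        left, _, rest = rest.partition("-")
    if "+" in rest:
        rest, _, right = rest.partition("+")
    return left, rest, right


def tri_labels_of(motions) -> list:
    """Per-position context-dependent labels of a motion string.

    sil is context-independent and acts as a context boundary: contexts
    never reach across a sil.
    """
    labels = []
    n = len(motions)
    for i, m in enumerate(motions):
        if m == SIL:
            labels.append(SIL)
            continue
        left = motions[i - 1] if i > 0 and motions[i - 1] != SIL else None
        right = motions[i + 1] if i < n - 1 and motions[i + 1] != SIL else None
        labels.append(tri_label(left, m, right))
    return labels


# ---------------------------------------------------------------------------
# the model set

@dataclass
class ModelSet:
    """Inventory of unit HMMs over a flat emission-state table."""

    emissions: list                      # list[GaussianMixtureState]
    units: dict                          # name -> UnitHMM
    dim: int
    var_floor: np.ndarray                # (d,)
    global_mean: np.ndarray
    global_var: np.ndarray
    context_dependent: bool = False
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ModelSet":
        return copy.deepcopy(self)

    @property
    def n_emissions(self) -> int:
        return len(self.emissions)

    def get_unit(self, label: str) -> UnitHMM:
        """Look up a unit model; unseen tri-motion contexts back off to the
        center unit."""
        u = self.units.get(label)
        if u is not None:
            return u
        _, center, _ = parse_tri(label)
        u = self.units.get(center)
        if u is None:
            raise KeyError(f"no model for unit {label!r} (center {center!r})")
        return u

    def labels_for(self, motions) -> list:
        return tri_labels_of(motions) if self.context_dependent else list(motions)

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "dim": self.dim,
            "context_dependent": self.context_dependent,
            "var_floor": self.var_floor.tolist(),
            "global_mean": self.global_mean.tolist(),
            "global_var": self.global_var.tolist(),
            "emissions": [
                {"weights": e.weights.tolist(), "means": e.means.tolist(),
                 "variances": e.variances.tolist()}
                for e in self.emissions
            ],
            "units": {
                name: {"state_ids": u.state_ids.tolist(), "stay": u.stay.tolist()}
                for name, u in self.units.items()
            },
            "meta": self.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        emissions = [GaussianMixtureState(np.array(e["weights"]),
                                          np.array(e["means"]),
                                          np.array(e["variances"]))
                     for e in obj["emissions"]]
        units = {name: UnitHMM(name, np.array(u["state_ids"]), np.array(u["stay"]))
                 for name, u in obj["units"].items()}
        return cls(emissions=emissions, units=units, dim=obj["dim"],
                   var_floor=np.array(obj["var_floor"]),
                   global_mean=np.array(obj["global_mean"]),
                   global_var=np.array(obj["global_var"]),
                   context_dependent=obj["context_dependent"],
                   meta=obj.get("meta", {}))


def _as_frames(fs) -> np.ndarray:
    if isinstance(fs, FeatureSequence):
        return fs.frames
    return np.atleast_2d(np.asarray(fs, dtype=float))


def flat_start(train, units, *, stay: float = 0.5,
               var_floor_frac: float = 1e-4) -> ModelSet:
    """Initialize one untied unit HMM per name from global data statistics.

    Every state starts as a single Gaussian with the global mean and
    diagonal covariance of the whole training set; all self-loop and
    forward transition probabilities start at 0.5.
    """
    mats = [_as_frames(fs) for fs in train]
    if not mats:
        raise ValueError("empty training set")
    allx = np.concatenate(mats, axis=0)
    mean = allx.mean(axis=0)
    var = allx.var(axis=0)
    d = allx.shape[1]
    floor = np.maximum(var_floor_frac * var, 1e-12)
    if np.any(var < floor) or len(allx) < 2:
        logger.warning("flat_start: degenerate data, variance floored")
    var = np.maximum(var, floor)
    emissions = []
    unit_map = {}
    for name in units:
        ids = np.arange(len(emissions), len(emissions) + N_STATES)
        for _ in range(N_STATES):
            emissions.append(GaussianMixtureState(
                np.array([1.0]), mean.copy()[None, :], var.copy()[None, :]))
        unit_map[name] = UnitHMM(name, ids, np.full(N_STATES, stay))
    return ModelSet(emissions=emissions, units=unit_map, dim=d,
                    var_floor=floor, global_mean=mean, global_var=var)


# ---------------------------------------------------------------------------
# chain compilation and the three DP passes

@dataclass
class Chain:
    """A motion sequence compiled to one linear left-to-right state chain."""

    labels: list            # per-unit labels (context-resolved)
    emis_ids: np.ndarray    # (S,) emission table indices
    log_stay: np.ndarray    # (S,)
    log_fwd: np.ndarray     # (S,)
    unit_index: np.ndarray  # (S,) which unit each chain state belongs to
    state_index: np.ndarray  # (S,) 0..3 within the unit

    @property
    def n_states(self) -> int:
        return len(self.emis_ids)


def compile_chain(ms: ModelSet, motions) -> Chain:
    labels = ms.labels_for(motions)
    emis, stay, uidx, sidx = [], [], [], []
    for i, lab in enumerate(labels):
        u = ms.get_unit(lab)
        emis.append(u.state_ids)
        stay.append(u.stay)
        uidx.extend([i] * N_STATES)
        sidx.extend(range(N_STATES))
    stay_arr = np.clip(np.concatenate(stay), 1e-8, 1.0 - 1e-8)
    return Chain(labels=labels,
                 emis_ids=np.concatenate(emis),
                 log_stay=np.log(stay_arr),
                 log_fwd=np.log1p(-stay_arr),
                 unit_index=np.array(uidx),
                 state_index=np.array(sidx))


def chain_emission_logliks(ms: ModelSet, chain: Chain, X: np.ndarray,
                           emission_matrix: np.ndarray | None = None) -> np.ndarray:
    """(T, S) per-chain-state emission log-likelihoods.

    ``emission_matrix`` (T, n_emissions) overrides the GMM evaluation; this
    is the hook used by the hybrid neural scorer.
    """
    distinct, inverse = np.unique(chain.emis_ids, return_inverse=True)
    if emission_matrix is not None:
        return emission_matrix[:, chain.emis_ids]
    cols = np.stack([ms.emissions[e].logpdf(X) for e in distinct], axis=1)
    return cols[:, inverse]


def _shift_down(a: np.ndarray) -> np.ndarray:
    """a[j-1] aligned at j; position 0 gets log-zero."""
    out = np.empty_like(a)
    out[0] = LZERO
    out[1:] = a[:-1]
    return out


def forward_loglik(ms: ModelSet, motions, fs,
                   emission_matrix: np.ndarray | None = None) -> float:
    """log P(X | motion sequence) summed over all admissible state paths.

    Returns -inf when the sequence is shorter than the minimum path
    (one frame per chain state).
    """
    X = _as_frames(fs)
    chain = compile_chain(ms, motions)
    if len(X) < chain.n_states:
        return float("-inf")
    logB = chain_emission_logliks(ms, chain, X, emission_matrix)
    alpha = np.full(chain.n_states, LZERO)
    alpha[0] = logB[0, 0]
    for t in range(1, len(X)):
        alpha = np.logaddexp(alpha + chain.log_stay,
                             _shift_down(alpha + chain.log_fwd)) + logB[t]
    return float(alpha[-1] + chain.log_fwd[-1])


def viterbi_align(ms: ModelSet, motions, fs,
                  emission_matrix: np.ndarray | None = None):
    """Best state path through the compiled chain.

    Returns ``(unit_segments, state_segments, loglik)`` where the segments
    tile the feature sequence exactly (frame indices, half-open).  On equal
    scores the self-loop is preferred, for determinism.
    """
    X = _as_frames(fs)
    chain = compile_chain(ms, motions)
    T, S = len(X), chain.n_states
    if T < S:
        raise InfeasibleAlignmentError(
            f"{T} frames cannot traverse {S} chain states")
    logB = chain_emission_logliks(ms, chain, X, emission_matrix)
    delta = np.full(S, LZERO)
    delta[0] = logB[0, 0]
    back = np.zeros((T, S), dtype=bool)  # True: came from j-1
    for t in range(1, T):
        stay_sc = delta + chain.log_stay
        fwd_sc = _shift_down(delta + chain.log_fwd)
        from_prev = fwd_sc > stay_sc          # strict: ties prefer stay
        back[t] = from_prev
        delta = np.where(from_prev, fwd_sc, stay_sc) + logB[t]
    loglik = float(delta[-1] + chain.log_fwd[-1])
    # backtrace from the mandatory final state
    path = np.empty(T, dtype=int)
    j = S - 1
    for t in range(T - 1, -1, -1):
        path[t] = j
        if t > 0 and back[t, j]:
            j -= 1
    if path[0] != 0:
        raise InfeasibleAlignmentError("no admissible path reaches state 0")
    unit_segments, state_segments = _segments_from_path(chain, motions, path)
    return unit_segments, state_segments, loglik, path, chain


def _segments_from_path(chain: Chain, motions, path: np.ndarray):
    unit_segs, state_segs = [], []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[t - 1]:
            j = path[t - 1]
            state_segs.append(LabelSegment(
                start, t, f"{chain.labels[chain.unit_index[j]]}[{chain.state_index[j]}]"))
            start = t
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or chain.unit_index[path[t]] != chain.unit_index[path[t - 1]]:
            j = path[t - 1]
            unit_segs.append(LabelSegment(start, t, motions[chain.unit_index[j]]))
            start = t
    return unit_segs, state_segs


# ---------------------------------------------------------------------------
# embedded Baum-Welch

@dataclass
class SuffStats:
    """Corpus sufficient statistics of one E-step."""

    loglik: float
    occ: np.ndarray        # (E, M_max) component occupancies
    sum_x: np.ndarray      # (E, M_max, d)
    sum_x2: np.ndarray     # (E, M_max, d)
    trans_stay: dict       # label -> (N_STATES,)
    trans_fwd: dict
    n_frames: int = 0


def accumulate_stats(ms: ModelSet, corpus,
                     emission_fn=None) -> SuffStats:
    """Forward-backward over an embedded-training corpus.

    ``corpus`` is an iterable of ``(features, motion_sequence)`` pairs.
    ``emission_fn(X) -> (T, n_emissions)`` optionally overrides the GMM
    emission evaluation.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    E = ms.n_emissions
    Mmax = max(e.n_components for e in ms.emissions)
    d = ms.dim
    occ = np.zeros((E, Mmax))
    sum_x = np.zeros((E, Mmax, d))
    sum_x2 = np.zeros((E, Mmax, d))
    trans_stay: dict = {}
    trans_fwd: dict = {}
    total_ll = 0.0
    n_frames = 0
    skipped = 0
    for fs, motions in corpus:
        X = _as_frames(fs)
        chain = compile_chain(ms, motions)
        T, S = len(X), chain.n_states
        if T < S:
            skipped += 1
            continue
        n_frames += T
        emat = emission_fn(X) if emission_fn is not None else None
        logB = chain_emission_logliks(ms, chain, X, emat)
        # forward
        log_alpha = np.full((T, S), LZERO)
        log_alpha[0, 0] = logB[0, 0]
        for t in range(1, T):
            log_alpha[t] = np.logaddexp(
                log_alpha[t - 1] + chain.log_stay,
                _shift_down(log_alpha[t - 1] + chain.log_fwd)) + logB[t]
        ll = log_alpha[-1, -1] + chain.log_fwd[-1]
        if not np.isfinite(ll) or ll <= LZERO / 2:
            skipped += 1
            n_frames -= T
            continue
        total_ll += ll
        # backward
        log_beta = np.full((T, S), LZERO)
        log_beta[-1, -1] = chain.log_fwd[-1]
        for t in range(T - 2, -1, -1):
            nxt = logB[t + 1] + log_beta[t + 1]
            stay_term = chain.log_stay + nxt
            fwd_term = np.full(S, LZERO)
            fwd_term[:-1] = chain.log_fwd[:-1] + nxt[1:]
            log_beta[t] = np.logaddexp(stay_term, fwd_term)
        gamma = np.exp(log_alpha + log_beta - ll)  # (T, S)
        # transition statistics
        xi_stay = np.exp(log_alpha[:-1] + chain.log_stay[None, :]
                         + logB[1:] + log_beta[1:] - ll).sum(axis=0)
        xi_fwd_t = (log_alpha[:-1, :-1] + chain.log_fwd[None, :-1]
                    + logB[1:, 1:] + log_beta[1:, 1:] - ll)
        xi_fwd = np.zeros(S)
        xi_fwd[:-1] = np.exp(xi_fwd_t).sum(axis=0)
        xi_fwd[-1] = gamma[-1, -1]  # exit arc
        for i, lab in enumerate(chain.labels):
            sl = slice(i * N_STATES, (i + 1) * N_STATES)
            key = ms.get_unit(lab).name
            trans_stay.setdefault(key, np.zeros(N_STATES))
            trans_fwd.setdefault(key, np.zeros(N_STATES))
            trans_stay[key] += xi_stay[sl]
            trans_fwd[key] += xi_fwd[sl]
        # emission statistics, per distinct emission id
        distinct = np.unique(chain.emis_ids)
        g_by_emis = np.zeros((T, len(distinct)))
        pos_of = {e: k for k, e in enumerate(distinct)}
        for j in range(S):
            g_by_emis[:, pos_of[chain.emis_ids[j]]] += gamma[:, j]
        for e in distinct:
            gme = ms.emissions[e]
            g = g_by_emis[:, pos_of[e]]
            if emat is not None:
                resp = np.ones((T, 1))
                comp_w = g[:, None] * resp
                occ[e, :1] += comp_w.sum(axis=0)
                sum_x[e, :1] += comp_w.T @ X
                sum_x2[e, :1] += comp_w.T @ (X * X)
                continue
            clp = gme.component_logpdf(X)  # (T, M)
            norm = clp - clp.max(axis=1, keepdims=True)
            resp = np.exp(norm)
            resp /= resp.sum(axis=1, keepdims=True)
            comp_w = g[:, None] * resp
            M = gme.n_components
            occ[e, :M] += comp_w.sum(axis=0)
            sum_x[e, :M] += comp_w.T @ X
            sum_x2[e, :M] += comp_w.T @ (X * X)
    if skipped:
        logger.warning("accumulate_stats: skipped %d infeasible/degenerate items", skipped)
    if n_frames == 0:
        raise ValueError("no trainable items in corpus")
    return SuffStats(loglik=float(total_ll), occ=occ, sum_x=sum_x, sum_x2=sum_x2,
                     trans_stay=trans_stay, trans_fwd=trans_fwd, n_frames=n_frames)


def _m_step(ms: ModelSet, stats: SuffStats, *, min_occ: float = 1e-3) -> ModelSet:
    new = ms.copy()
    for e, gme in enumerate(new.emissions):
        M = gme.n_components
        occ = stats.occ[e, :M]
        tot = occ.sum()
        if tot < min_occ:
            logger.debug("emission %d received no occupancy; kept", e)
            continue
        keep = occ > min_occ
        weights = np.where(keep, occ, gme.weights * tot)  # keep old share if starved
        weights = weights / weights.sum()
        means = np.where(keep[:, None], stats.sum_x[e, :M] / np.maximum(occ, min_occ)[:, None],
                         gme.means)
        var = np.where(keep[:, None],
                       stats.sum_x2[e, :M] / np.maximum(occ, min_occ)[:, None] - means ** 2,
                       gme.variances)
        var = np.maximum(var, new.var_floor[None, :])
        new.emissions[e] = GaussianMixtureState(weights, means, var)
    for name, u in new.units.items():
        if name not in stats.trans_stay:
            continue
        s = stats.trans_stay[name]
        f = stats.trans_fwd[name]
        tot = s + f
        stay = np.where(tot > min_occ, s / np.maximum(tot, min_occ), u.stay)
        u.stay = np.clip(stay, 1e-4, 1.0 - 1e-4)
    return new


def baum_welch_iteration(ms: ModelSet, corpus):
    """One embedded EM iteration; returns (updated model, pre-update corpus
    log-likelihood)."""
    stats = accumulate_stats(ms, corpus)
    return _m_step(ms, stats), stats.loglik


def train_baum_welch(ms: ModelSet, corpus, n_iter: int = 5):
    """Run ``n_iter`` EM iterations; returns (model, per-iteration logliks)."""
    lls = []
    for _ in range(n_iter):
        ms, ll = baum_welch_iteration(ms, corpus)
        lls.append(ll)
    return ms, lls


def split_mixtures(ms: ModelSet, *, perturb: float = 0.2) -> ModelSet:
    """Double every state's component count by perturbing means +-0.2 sd."""
    new = ms.copy()
    for e, gme in enumerate(new.emissions):
        sd = np.sqrt(gme.variances)
        means = np.concatenate([gme.means + perturb * sd,
                                gme.means - perturb * sd], axis=0)
        weights = np.concatenate([gme.weights, gme.weights]) / 2.0
        variances = np.concatenate([gme.variances, gme.variances], axis=0)
        new.emissions[e] = GaussianMixtureState(weights, means, variances)
    return new


# ---------------------------------------------------------------------------
# tri-motion expansion and decision-tree state clustering

def expand_to_trimotion(ms: ModelSet, corpus_motions) -> ModelSet:
    """Clone one unit HMM per distinct tri-motion label in the corpus.

    The mono-motion models are kept in the inventory so unseen contexts at
    test time back off to their center unit; sil stays context-independent.
    """
    new = ms.copy()
    seen = set()
    for motions in corpus_motions:
        seen.update(tri_labels_of(motions))
    for lab in sorted(seen):
        if lab in new.units:
            continue
        _, center, _ = parse_tri(lab)
        base = new.units[center]
        ids = np.arange(len(new.emissions), len(new.emissions) + N_STATES)
        for sid in base.state_ids:
            src = new.emissions[sid]
            new.emissions.append(GaussianMixtureState(
                src.weights.copy(), src.means.copy(), src.variances.copy()))
        new.units[lab] = UnitHMM(lab, ids, base.stay.copy())
    new.context_dependent = True
    return new


@dataclass(frozen=True)
class ContextQuestion:
    """Is the left/right context a member of a unit subset?"""

    side: str            # "left" or "right"
    units: frozenset     # unit names; BOUNDARY marks "no context"
    name: str = ""

    def applies(self, label: str) -> bool:
        left, _, right = parse_tri(label)
        ctx = left if self.side == "left" else right
        return (ctx if ctx is not None else BOUNDARY) in self.units


BOUNDARY = "#"


def default_questions(units) -> list:
    """Singleton questions per unit plus direction-family groups."""
    families = {
        "horizontal": {"left", "right"},
        "vertical": {"up", "down"},
        "diagonal": {"upper_left", "upper_right", "lower_left", "lower_right"},
        "boundary": {BOUNDARY},
    }
    qs = []
    for side in ("left", "right"):
        for u in units:
            if u == SIL:
                continue
            qs.append(ContextQuestion(side, frozenset([u]), f"{side}={u}"))
        for fam, members in families.items():
            qs.append(ContextQuestion(side, frozenset(members), f"{side}:{fam}"))
    return qs


def collect_tying_stats(ms: ModelSet, corpus) -> dict:
    """Single-Gaussian sufficient stats per (tri label, state index).

    Run on a context-dependent, single-component model set: returns
    ``{(label, k): (occ, sum_x, sum_x2)}`` aggregated from forward-backward
    posteriors.
    """
    stats = accumulate_stats(ms, corpus)
    out = {}
    for label, u in ms.units.items():
        for k in range(N_STATES):
            e = u.state_ids[k]
            occ = float(stats.occ[e, 0])
            if occ <= 0:
                continue
            out[(label, k)] = (occ, stats.sum_x[e, 0].copy(), stats.sum_x2[e, 0].copy())
    return out


def _pooled_loglik(occ, sx, sx2, floor) -> float:
    """Log-likelihood of pooled stats under their own single Gaussian."""
    if occ <= 0:
        return 0.0
    mean = sx / occ
    var = np.maximum(sx2 / occ - mean ** 2, floor)
    d = len(mean)
    return float(-0.5 * occ * (d * (np.log(2 * np.pi) + 1.0) + np.log(var).sum()))


@dataclass
class StateTying:
    """Map (tri label, state index) -> tied emission id, plus the trees."""

    mapping: dict                 # (label, k) -> tied id
    n_tied: int
    trees: dict = field(default_factory=dict)  # (center, k) -> nested split record


def cluster_states(stats: dict, questions, *, min_gain: float = 0.0,
                   max_states_per_tree: int = 8,
                   var_floor: np.ndarray | float = 1e-8) -> StateTying:
    """Greedy decision-tree clustering of context-dependent states.

    One tree per (center unit, state index).  At each leaf the split
    maximizing the single-Gaussian log-likelihood gain is taken, until the
    best gain falls below ``min_gain`` or the tree has
    ``max_states_per_tree`` leaves.
    """
    if not stats:
        raise ValueError("empty tying stats")
    floor = np.asarray(var_floor, dtype=float)
    groups: dict = {}
    for (label, k), s in stats.items():
        _, center, _ = parse_tri(label)
        groups.setdefault((center, k), []).append((label, s))

    mapping: dict = {}
    trees: dict = {}
    next_id = 0
    for (center, k), members in sorted(groups.items()):
        leaves = [[m for m in members]]
        records = []
        while len(leaves) < max_states_per_tree:
            best = None
            for li, leaf in enumerate(leaves):
                if len(leaf) < 2:
                    continue
                p_occ = sum(s[0] for _, s in leaf)
                p_sx = sum(s[1] for _, s in leaf)
                p_sx2 = sum(s[2] for _, s in leaf)
                parent_ll = _pooled_loglik(p_occ, p_sx, p_sx2, floor)
                for q in questions:
                    yes = [m for m in leaf if q.applies(m[0])]
                    no = [m for m in leaf if not q.applies(m[0])]
                    if not yes or not no:
                        continue
                    ll = sum(
                        _pooled_loglik(sum(s[0] for _, s in part),
                                       sum(s[1] for _, s in part),
                                       sum(s[2] for _, s in part), floor)
                        for part in (yes, no))
                    gain = ll - parent_ll
                    if best is None or gain > best[0]:
                        best = (gain, li, q, yes, no)
            if best is None or best[0] < min_gain:
                break
            gain, li, q, yes, no = best
            leaves[li] = yes
            leaves.append(no)
            records.append({"question": q.name or f"{q.side}:{sorted(q.units)}",
                            "gain": gain})
        for leaf in leaves:
            for label, _ in leaf:
                mapping[(label, k)] = next_id
            next_id += 1
        trees[(center, k)] = records
    return StateTying(mapping=mapping, n_tied=next_id, trees=trees)


def apply_tying(ms: ModelSet, tying: StateTying, stats: dict) -> ModelSet:
    """Rebuild the model set with one pooled single Gaussian per tied state."""
    new = ms.copy()
    d = new.dim
    pooled = [(0.0, np.zeros(d), np.zeros(d)) for _ in range(tying.n_tied)]
    for key, tid in tying.mapping.items():
        if key not in stats:
            continue
        occ, sx, sx2 = stats[key]
        o, a, b = pooled[tid]
        pooled[tid] = (o + occ, a + sx, b + sx2)
    emissions = []
    for occ, sx, sx2 in pooled:
        if occ > 0:
            mean = sx / occ
            var = np.maximum(sx2 / occ - mean ** 2, new.var_floor)
        else:
            mean = new.global_mean.copy()
            var = new.global_var.copy()
        emissions.append(GaussianMixtureState(np.array([1.0]), mean[None, :],
                                              var[None, :]))
    # untied units (center backoffs, sil, unseen) keep their own states
    units = {}
    for name, u in new.units.items():
        ids = []
        for k in range(N_STATES):
            if (name, k) in tying.mapping:
                ids.append(tying.mapping[(name, k)])
            else:
                src = new.emissions[u.state_ids[k]]
                ids.append(len(emissions))
                emissions.append(GaussianMixtureState(
                    np.array([1.0]), src.means.mean(axis=0)[None, :],
                    src.variances.mean(axis=0)[None, :]))
        units[name] = UnitHMM(name, np.array(ids), u.stay.copy())
    new.emissions = emissions
    new.units = units
    new.meta["n_tied_states"] = tying.n_tied
    return new


# ---------------------------------------------------------------------------
# the standard training schedule

def standard_training(corpus, units, *, n_components: int = 16,
                      iters_per_stage: int = 5, tri_motion: bool = False,
                      tying_min_gain: float | None = None,
                      tying_max_states: int = 8, verbose: bool = False):
    """Flat start -> EM -> iterated {split, EM} until ``n_components`` ->
    optional tri-motion cloning + decision-tree tying -> final EM.

    ``corpus`` is a list of (features, motion_sequence) pairs.  Returns
    ``(model, history)`` where history is the list of corpus log-likelihoods
    of every EM iteration in order.
    """
    feats = [c[0] for c in corpus]
    ms = flat_start(feats, units)
    history = []
    ms, lls = train_baum_welch(ms, corpus, iters_per_stage)
    history.extend(lls)
    if tri_motion:
        ms = expand_to_trimotion(ms, [c[1] for c in corpus])
        stats = collect_tying_stats(ms, corpus)
        tying = cluster_states(stats, default_questions(units),
                               min_gain=(tying_min_gain if tying_min_gain is not None
                                         else 0.0),
                               max_states_per_tree=tying_max_states,
                               var_floor=ms.var_floor)
        ms = apply_tying(ms, tying, stats)
        ms, lls = train_baum_welch(ms, corpus, iters_per_stage)
        history.extend(lls)
    m = 1
    while m < n_components:
        ms = split_mixtures(ms)
        m *= 2
        ms, lls = train_baum_welch(ms, corpus, iters_per_stage)
        history.extend(lls)
        if verbose:
            logger.info("reached %d components, loglik %.1f", m, lls[-1])
    ms, lls = train_baum_welch(ms, corpus, iters_per_stage)
    history.extend(lls)
    return ms, history
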