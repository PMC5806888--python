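"""Continuous recognition: time-synchronous Viterbi beam search.

The decode graph is the protocol lexicon expanded to unit-HMM state
chains: one linear sub-chain per character (its motion expansion with
inter-stroke sil, plus a trailing sil unit) and a leading sil chain at the
start.  Because every sub-chain is strictly left-to-right, the in-chain
Viterbi update is a vectorized shift-and-max over the whole state space;
only character entries need per-hypothesis work.

Hypotheses are recombined at (graph state, language-model state): the
search keeps one score array per distinct truncated character history, and
each state carries its full emitted history so recombination never loses
the output string.  Character exits pay the scaled LM log-probability and
the insertion penalty; the final hypothesis additionally pays the
end-of-sentence LM event.  Tri-motion contexts never cross a character
boundary because sil is a context boundary, so the sub-chains compose
exactly like the training chains.

Progressive output: after each frame the hypothesis posterior (normalized
exp(score) over active states) is thresholded, and a character is
committed as soon as every surviving hypothesis agrees on it; with the
threshold at 0 the incremental result equals the batch decode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSequence
from .hmm import N_STATES, ModelSet, tri_labels_of, viterbi_align
from .io import Transcription
from .lm import BOS, EOS, NGramModel
from .protocol import SIL, Protocol

__all__ = [
    "BeamConfig",
    "DecodeGraph",
    "DecodeResult",
    "EmptyBeamError",
    "build_graph",
    "decode",
    "progressive_decode",
]

NEG_INF = -np.inf


class EmptyBeamError(RuntimeError):
    """Every hypothesis was pruned (beam too tight for the input)."""


@dataclass(frozen=True)
class BeamConfig:
    """Search-control parameters.

    ``beam`` is a log-score margin under the best hypothesis (``inf``
    disables pruning); ``max_active_contexts`` caps the number of distinct
    LM histories kept alive; ``progressive_threshold`` prunes hypothesis
    posteriors during progressive output.
    """

    beam: float = 120.0
    max_active_contexts: int = 32
    lm_scale: float = 1.0
    insertion_penalty: float = 0.0
    progressive_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if self.beam <= 0:
            raise ValueError("beam must be positive")
        if not (0.0 <= self.progressive_threshold < 1.0):
            raise ValueError("progressive_threshold must lie in [0, 1)")


@dataclass
class DecodeGraph:
    """Lexicon network compiled to flat left-to-right state arrays."""

    ms: ModelSet
    chars: list                 # character symbols, graph order
    emis_ids: np.ndarray        # (G,)
    log_stay: np.ndarray        # (G,)
    log_fwd: np.ndarray         # (G,)
    head: np.ndarray            # (n_chars,) entry state per character
    tail: np.ndarray            # (n_chars,) exit state per character
    start_tail: int             # exit state of the leading sil chain
    is_head: np.ndarray         # (G,) True at chain-entry states

    @property
    def n_states(self) -> int:
        return len(self.emis_ids)


def build_graph(protocol: Protocol, ms: ModelSet) -> DecodeGraph:
    """Compile the lexicon into the search network.

    Each character contributes the chain of its motion expansion plus a
    trailing sil unit; unseen tri-motion contexts back off to their center
    unit inside ``ModelSet.get_unit``.
    """
    emis, stay = [], []
    is_head = []

    def add_chain(motions):
        labels = ms.labels_for(motions) if ms.context_dependent else list(motions)
        first = N_STATES * len(emis)
        for li, lab in enumerate(labels):
            u = ms.get_unit(lab)
            emis.append(u.state_ids)
            stay.append(u.stay)
            is_head.extend([li == 0 and s == 0 for s in range(N_STATES)])
        return first, N_STATES * len(emis) - 1

    # leading sil chain
    _start_head, start_tail = add_chain([SIL])
    heads, tails, chars = [], [], []
    for char in protocol.characters:
        motions = list(protocol.expand_character(char)) + [SIL]
        if not motions:
            raise ValueError(f"character {char!r} has an empty expansion")
        h, t = add_chain(motions)
        heads.append(h)
        tails.append(t)
        chars.append(char)
    stay_arr = np.clip(np.concatenate(stay), 1e-8, 1 - 1e-8)
    return DecodeGraph(
        ms=ms,
        chars=chars,
        emis_ids=np.concatenate(emis),
        log_stay=np.log(stay_arr),
        log_fwd=np.log1p(-stay_arr),
        head=np.array(heads),
        tail=np.array(tails),
        start_tail=start_tail,
        is_head=np.array(is_head, dtype=bool),
    )


@dataclass
class DecodeResult:
    """Best hypothesis with its alignment and score decomposition."""

    characters: Transcription
    unit_segments: list
    state_segments: list
    score: float
    acoustic_score: float
    lm_score: float
    insertion_penalty_total: float
    char_emission_frames: list = field(default_factory=list)  # (char, end frame)
    commits: list = field(default_factory=list)  # progressive (frame, char)


def _emission_matrix_for(graph: DecodeGraph, X: np.ndarray,
                         emission_matrix: np.ndarray | None) -> np.ndarray:
    if emission_matrix is not None:
        return emission_matrix[:, graph.emis_ids]
    distinct, inverse = np.unique(graph.emis_ids, return_inverse=True)
    cols = np.stack([graph.ms.emissions[e].logpdf(X) for e in distinct], axis=1)
    return cols[:, inverse]


class _LMView:
    """Vectorized conditional log-probabilities over the graph's characters."""

    def __init__(self, lm: NGramModel | None, chars, lm_scale: float):
        self.lm = lm
        self.chars = list(chars)
        self.scale = lm_scale
        self._cache: dict = {}
        if lm is None:
            self.order = 1
            self.uniform = -math.log(len(self.chars) + 1)  # chars + end event
        else:
            self.order = lm.order

    def key_of(self, hist: tuple) -> tuple:
        return ((BOS,) + hist)[-(self.order - 1):] if self.order > 1 else ()

    def vector(self, hist: tuple) -> np.ndarray:
        """Scaled log P(char | hist) for every graph character."""
        if self.lm is None:
            return np.full(len(self.chars), self.scale * self.uniform)
        key = self.key_of(hist)
        vec = self._cache.get(key)
        if vec is None:
            full = dict(zip(self.lm.vocab, self.lm.logprob_vector((BOS,) + hist)))
            vec = self.scale * np.array(
                [full.get(c, -1e10) for c in self.chars])
            self._cache[key] = vec
        return vec

    def end(self, hist: tuple) -> float:
        if self.lm is None:
            return self.scale * self.uniform
        return self.scale * self.lm.cond_logprob(EOS, (BOS,) + hist)


def _shift_down_scores(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[0] = NEG_INF
    out[1:] = a[:-1]
    return out


def _shift_down_obj(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[0] = a[0]
    out[1:] = a[:-1]
    return out


class _Beam:
    """The per-frame search state: one (scores, histories) pair per LM key."""

    def __init__(self, graph: DecodeGraph, lmv: _LMView, cfg: BeamConfig):
        self.graph = graph
        self.lmv = lmv
        self.cfg = cfg
        g = graph.n_states
        scores = np.full(g, NEG_INF)
        hist = np.empty(g, dtype=object)
        hist[:] = ((),) * g
        self.contexts = {lmv.key_of(()): (scores, hist)}
        self.frame = -1

    def start(self, logB0: np.ndarray) -> None:
        (scores, _hist) = next(iter(self.contexts.values()))
        scores[0] = logB0[0]  # state 0 of the leading sil chain
        self.frame = 0

    def step(self, logBt: np.ndarray) -> None:
        g = self.graph
        cfg = self.cfg
        new: dict = {}
        # in-chain propagation
        for key, (sc, hist) in self.contexts.items():
            stay = sc + g.log_stay
            fwd = _shift_down_scores(sc + g.log_fwd)
            fwd[g.is_head] = NEG_INF
            take_fwd = fwd > stay
            pre = np.where(take_fwd, fwd, stay)
            ph = np.where(take_fwd, _shift_down_obj(hist), hist)
            if key in new:
                osc, ohist = new[key]
                better = pre > osc
                new[key] = (np.where(better, pre, osc), np.where(better, ph, ohist))
            else:
                new[key] = (pre, ph)
        # character entries (from the start chain and every character tail)
        best_pre = max((s.max() for s, _ in new.values()), default=NEG_INF)
        prune_at = best_pre - cfg.beam if np.isfinite(cfg.beam) else NEG_INF
        for key, (sc, hist) in self.contexts.items():
            exits = np.append(sc[g.tail] + g.log_fwd[g.tail],
                              sc[g.start_tail] + g.log_fwd[g.start_tail])
            order = np.argsort(exits)[::-1]
            for src in order:
                es = exits[src]
                if not np.isfinite(es) or es < prune_at:
                    break
                h = hist[g.tail[src]] if src < len(g.tail) else hist[g.start_tail]
                cand = es + self.lmv.vector(h) - cfg.insertion_penalty
                keep = cand >= prune_at
                if not keep.any():
                    continue
                for j in np.nonzero(keep)[0]:
                    nh = h + (g.chars[j],)
                    nk = self.lmv.key_of(nh)
                    tgt = new.get(nk)
                    if tgt is None:
                        nsc = np.full(g.n_states, NEG_INF)
                        nhist = np.empty(g.n_states, dtype=object)
                        nhist[:] = ((),) * g.n_states
                        new[nk] = tgt = (nsc, nhist)
                    nsc, nhist = tgt
                    hj = g.head[j]
                    if cand[j] > nsc[hj]:
                        nsc[hj] = cand[j]
                        nhist[hj] = nh
        # add emissions, prune
        best = NEG_INF
        for key, (sc, hist) in new.items():
            sc += logBt
            m = sc.max()
            if m > best:
                best = m
        if not np.isfinite(best):
            raise EmptyBeamError(f"all hypotheses pruned at frame {self.frame + 1}")
        if np.isfinite(cfg.beam):
            new = {k: v for k, v in new.items() if v[0].max() >= best - cfg.beam}
        if len(new) > cfg.max_active_contexts:
            keys = sorted(new, key=lambda k: new[k][0].max(), reverse=True)
            new = {k: new[k] for k in keys[: cfg.max_active_contexts]}
        self.contexts = new
        self.frame += 1

    def threshold_prune(self, threshold: float) -> None:
        """Remove hypotheses whose normalized posterior is below threshold."""
        if threshold <= 0.0:
            return
        from scipy.special import logsumexp
        allsc = np.concatenate([sc for sc, _ in self.contexts.values()])
        finite = allsc[np.isfinite(allsc)]
        if finite.size == 0:
            return
        log_norm = logsumexp(finite)
        cut = math.log(threshold) + log_norm
        for sc, _ in self.contexts.values():
            sc[sc < cut] = NEG_INF
        self.contexts = {k: v for k, v in self.contexts.items()
                         if np.isfinite(v[0]).any()}

    def surviving_histories(self):
        for sc, hist in self.contexts.values():
            for j in np.nonzero(np.isfinite(sc))[0]:
                yield hist[j]

    def best_final(self):
        """Best complete hypothesis: exit a character-tail (or the start
        chain for the empty output) and pay the LM end event."""
        g = self.graph
        best = (NEG_INF, ())
        for sc, hist in self.contexts.values():
            for pos in list(g.tail) + [g.start_tail]:
                s = sc[pos] + g.log_fwd[pos]
                if not np.isfinite(s):
                    continue
                total = s + self.lmv.end(hist[pos])
                if total > best[0]:
                    best = (float(total), hist[pos])
        return best


def _prepare(features):
    if isinstance(features, FeatureSequence):
        return np.asarray(features.frames, dtype=float)
    return np.atleast_2d(np.asarray(features, dtype=float))


def _finish(graph: DecodeGraph, protocol: Protocol, X, total: float, chars: tuple,
            cfg: BeamConfig, emission_matrix, commits) -> DecodeResult:
    """Assemble the result: forced alignment of the winning character
    sequence plus the score decomposition."""
    motions = protocol.compile_text(chars)
    emat = None
    if emission_matrix is not None:
        emat = emission_matrix
    try:
        unit_segs, state_segs, ac, _path, _chain = viterbi_align(
            graph.ms, motions, X, emission_matrix=emat)
    except Exception:
        unit_segs, state_segs, ac = [], [], float("nan")
    n = len(chars)
    pen = -cfg.insertion_penalty * n
    lm_total = total - ac - pen if np.isfinite(ac) else float("nan")
    char_times = []
    if unit_segs:
        # character ends at the frame where its trailing sil begins
        ci = 0
        per_char = []
        for char in chars:
            per_char.append(len(protocol.expand_character(char)))
        seg_i = 1  # skip leading sil
        for k, char in enumerate(chars):
            seg_i += per_char[k]
            end = unit_segs[min(seg_i, len(unit_segs) - 1)].start
            char_times.append((char, int(end)))
            seg_i += 1  # trailing/inter-character sil
    return DecodeResult(
        characters=Transcription(chars, tier="character"),
        unit_segments=unit_segs,
        state_segments=state_segs,
        score=float(total),
        acoustic_score=float(ac),
        lm_score=float(lm_total),
        insertion_penalty_total=float(pen),
        char_emission_frames=char_times,
        commits=list(commits),
    )


def decode(features, graph: DecodeGraph, protocol: Protocol,
           lm: NGramModel | None = None, cfg: BeamConfig | None = None,
           emission_matrix: np.ndarray | None = None) -> DecodeResult:
    """Batch Viterbi beam decoding of a feature sequence.

    ``emission_matrix`` (T, n_emissions) switches the acoustic score from
    the model set's GMMs to an external scorer (the hybrid network).
    """
    cfg = cfg or BeamConfig()
    X = _prepare(features)
    logB = _emission_matrix_for(graph, X, emission_matrix)
    lmv = _LMView(lm, graph.chars, cfg.lm_scale)
    beam = _Beam(graph, lmv, cfg)
    beam.start(logB[0])
    for t in range(1, len(X)):
        beam.step(logB[t])
    total, chars = beam.best_final()
    if not np.isfinite(total):
        raise EmptyBeamError("no complete hypothesis survived")
    return _finish(graph, protocol, X, total, chars, cfg, emission_matrix, [])


def progressive_decode(features, graph: DecodeGraph, protocol: Protocol,
                       lm: NGramModel | None = None,
                       cfg: BeamConfig | None = None,
                       emission_matrix: np.ndarray | None = None) -> DecodeResult:
    """Frame-by-frame decoding with posterior-threshold character commits.

    A character is committed at the first frame where, after removing
    hypotheses whose posterior falls below ``cfg.progressive_threshold``,
    every surviving hypothesis agrees on it.  ``commits`` on the result
    lists (frame, char) pairs; with threshold 0 the final output equals
    the batch decode.
    """
    cfg = cfg or BeamConfig()
    X = _prepare(features)
    logB = _emission_matrix_for(graph, X, emission_matrix)
    lmv = _LMView(lm, graph.chars, cfg.lm_scale)
    beam = _Beam(graph, lmv, cfg)
    beam.start(logB[0])
    commits = []
    n_committed = 0
    for t in range(1, len(X)):
        beam.step(logB[t])
        beam.threshold_prune(cfg.progressive_threshold)
        prefix = None
        for h in beam.surviving_histories():
            if prefix is None:
                prefix = h
            else:
                k = 0
                for a, b in zip(prefix, h):
                    if a != b:
                        break
                    k += 1
                prefix = prefix[:k]
            if len(prefix) <= n_committed:
                prefix = None
                break
        if prefix is not None and len(prefix) > n_committed:
            for c in prefix[n_committed:]:
                commits.append((t, c))
            n_committed = len(prefix)
    total, chars = beam.best_final()
    if not np.isfinite(total):
        raise EmptyBeamError("no complete hypothesis survived")
    for c in chars[n_committed:]:
        commits.append((len(X) - 1, c))
    return _finish(graph, protocol, X, total, chars, cfg, emission_matrix, commits)
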