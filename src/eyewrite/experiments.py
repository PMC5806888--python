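"""Canned end-to-end experiments on synthetic data.

Three experiment designs mirror the system's evaluation protocol at desk
scale: an isolated-stroke comparison of the DTW baseline against unit
HMMs, continuous user-dependent recognition (GMM-HMM and the hybrid
network), and a user-adaptation sweep starting from a user-independent
model.  Every experiment is deterministic given its seed block.

Desk-scale study conditions (chosen once; see the methods note): two
synthetic users, 100 training words x 3 repetitions per user, 10 test
sentences of 5-12 characters, 4 Gaussian components per state, 4 EM
iterations per training stage, a 5-gram character LM trained on sampled
word text with the test sentences excluded.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import adapt as adapt_mod
from . import decoder, dtw, hmm, lm as lm_mod, metrics, nn, synth
from .features import (FeatureSequence, append_deltas, apply_decorrelator,
                       fit_decorrelator, join_pairs, splice)
from .preprocess import make_baseform
from .protocol import Protocol, SIL, default_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "continuous_features",
    "isolated_features",
    "default_profiles",
    "build_continuous_dataset",
    "train_continuous_gmm",
    "HybridModel",
    "train_hybrid",
    "evaluate_cer",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# feature pipelines

def continuous_features(rec) -> FeatureSequence:
    """Raw 1 kHz -> 50 Hz baseform -> 12-dim expanded stream at 25 Hz."""
    bf = make_baseform(rec, "continuous")
    fs = FeatureSequence(bf.frames, bf.frame_rate_hz)
    return join_pairs(append_deltas(fs))


def isolated_features(rec) -> FeatureSequence:
    """Raw 1 kHz -> 125 Hz baseform -> 12-dim expanded stream at 62.5 Hz."""
    bf = make_baseform(rec, "isolated")
    fs = FeatureSequence(bf.frames, bf.frame_rate_hz)
    return join_pairs(append_deltas(fs))


# ---------------------------------------------------------------------------
# configuration

def default_profiles():
    """Two synthetic users: a nominal writer and a shifted writer with
    different channel gains, speed, crosstalk and drift."""
    return [
        synth.UserProfile(name="u001", seed=11),
        synth.UserProfile(name="u002", h_scale=1.25, v_scale=0.80,
                          speed_scale=1.15, crosstalk_deg=12.0,
                          drift_scale=1.3, seed=22),
    ]


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_train_words: int = 100
    n_reps: int = 3
    n_test_sentences: int = 10
    sentence_chars: tuple = (5, 12)
    n_components: int = 4
    iters_per_stage: int = 4
    tri_motion: bool = False
    lm_order: int = 5
    lm_sentences: int = 4000
    beam: decoder.BeamConfig = field(default_factory=decoder.BeamConfig)
    isolated_reps: int = 10
    adaptation_amounts: tuple = (5, 20, 100)
    output_dir: str | None = None


# ---------------------------------------------------------------------------
# dataset construction

@dataclass
class ContinuousDataset:
    protocol: Protocol
    words: list
    sentences: list
    train: dict        # user -> list of (features, motions, text)
    test: dict         # user -> list of (features, text, duration_s)
    lm: lm_mod.NGramModel
    profiles: list
    synth_cfg: synth.SynthConfig


def build_continuous_dataset(cfg: ExperimentConfig,
                             protocol: Protocol | None = None,
                             profiles=None) -> ContinuousDataset:
    """Render and featurize the continuous train/test corpus for all users."""
    protocol = protocol or default_protocol()
    profiles = profiles if profiles is not None else default_profiles()
    scfg = synth.SynthConfig(seed=cfg.seed)
    words = synth.make_word_list(protocol, cfg.n_train_words, seed=cfg.seed)
    sentences = synth.make_sentences(words, cfg.n_test_sentences,
                                     seed=cfg.seed + 101,
                                     min_chars=cfg.sentence_chars[0],
                                     max_chars=cfg.sentence_chars[1])
    lm_text = synth.sample_text(words, cfg.lm_sentences, seed=cfg.seed + 202,
                                exclude=sentences)
    ngram = lm_mod.train_ngram([list(s) for s in lm_text], order=cfg.lm_order,
                               vocab=list(protocol.characters) + [lm_mod.EOS])
    train, test = {}, {}
    for prof in profiles:
        items = synth.generate_corpus(words, protocol, prof, scfg,
                                      n_reps=cfg.n_reps)
        train[prof.name] = [
            (continuous_features(it["recording"]), it["motions"], it["text"])
            for it in items
        ]
        tst = []
        for i, s in enumerate(sentences):
            rec, _segs = synth.render_motions(
                protocol.compile_text(s), prof, scfg,
                item_seed=(900_000 + i) & 0x7FFFFFFF)
            tst.append((continuous_features(rec), s, rec.duration_s))
        test[prof.name] = tst
    return ContinuousDataset(protocol=protocol, words=words,
                             sentences=sentences, train=train, test=test,
                             lm=ngram, profiles=profiles, synth_cfg=scfg)


# ---------------------------------------------------------------------------
# model training

def train_continuous_gmm(train_items, protocol: Protocol,
                         cfg: ExperimentConfig) -> hmm.ModelSet:
    corpus = [(fs, motions) for fs, motions, _text in train_items]
    ms, _history = hmm.standard_training(
        corpus, protocol.motion_alphabet(),
        n_components=cfg.n_components,
        iters_per_stage=cfg.iters_per_stage,
        tri_motion=cfg.tri_motion)
    return ms


@dataclass
class HybridModel:
    """Hybrid network scorer: MLP + state prior + frozen front-end."""

    mlp: nn.MLP
    prior: nn.StatePrior
    decorrelator: object
    context: int = 5

    def emission_matrix(self, fs: FeatureSequence) -> np.ndarray:
        spliced = splice(fs, self.context)
        dec = apply_decorrelator(self.decorrelator, spliced)
        return nn.state_scaled_loglik(self.mlp, dec.frames, self.prior)


def train_hybrid(ms: hmm.ModelSet, train_items, *, seed: int = 0,
                 epochs: int = 20, context: int = 5,
                 max_fit_frames: int = 20000) -> HybridModel:
    """Build the hybrid NN-HMM from the trained GMM-HMM.

    Frames are labelled with tied-state (emission-id) targets by Viterbi
    alignment under the GMM system, spliced (+-context) and decorrelated
    by PCA fitted on the training frames only, then the network is trained
    with the standard schedule.
    """
    feats, targets = [], []
    for fs, motions, _text in train_items:
        try:
            _u, _s, _ll, path, chain = hmm.viterbi_align(ms, motions, fs)
        except hmm.InfeasibleAlignmentError:
            continue
        feats.append(splice(fs, context).frames)
        targets.append(chain.emis_ids[path])
    X = np.concatenate(feats, axis=0)
    y = np.concatenate(targets)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    fit_idx = rng.choice(len(X), size=min(max_fit_frames, len(X)), replace=False)
    # whitened components: the SGD schedule expects unit-scale inputs
    dec = fit_decorrelator(X[fit_idx], whiten=True)
    Xd = ((X - dec.mean) @ dec.rotation) / dec.scale
    K = ms.n_emissions
    sched = nn.TrainSchedule(epochs=epochs, seed=seed)
    mlp, history = nn.train_mlp(Xd, y, n_classes=K, sched=sched)
    logger.info("hybrid training: final holdout acc %.3f",
                history[-1]["holdout_accuracy"])
    prior = nn.StatePrior.from_counts(np.bincount(y, minlength=K))
    return HybridModel(mlp=mlp, prior=prior, decorrelator=dec, context=context)


# ---------------------------------------------------------------------------
# evaluation

def evaluate_cer(test_items, graph: decoder.DecodeGraph, protocol: Protocol,
                 ngram, beam_cfg: decoder.BeamConfig,
                 hybrid: HybridModel | None = None):
    """Corpus CER of a decoder configuration over (features, text, dur) items."""
    errors = 0
    ref_len = 0
    hyps = []
    for fs, text, _dur in test_items:
        emat = hybrid.emission_matrix(fs) if hybrid is not None else None
        try:
            res = decoder.decode(fs, graph, protocol, ngram, beam_cfg,
                                 emission_matrix=emat)
            hyp = "".join(res.characters.symbols)
        except decoder.EmptyBeamError:
            hyp = ""
        _cer, counts = metrics.character_error_rate(text, hyp)
        errors += counts.total
        ref_len += len(text)
        hyps.append(hyp)
    return errors / ref_len, hyps


# ---------------------------------------------------------------------------
# canned experiments

def _isolated_dataset(protocol: Protocol, profile, scfg, n_reps: int):
    """Render isolated stroke items: (features, stroke_id) pairs."""
    items = []
    for rep in range(n_reps):
        for sid in sorted(protocol.strokes):
            motions = (SIL,) + protocol.motions_of_stroke(sid) + (SIL,)
            rec, _segs = synth.render_motions(
                motions, profile, scfg,
                item_seed=(rep * 131 + sid) & 0x7FFFFFFF)
            items.append((isolated_features(rec), sid))
    return items


def _hmm_isolated_classifier(train_items, test_items, protocol, *,
                             n_components: int = 2, iters: int = 3):
    """Per-stroke unit HMMs; classification by forward log-likelihood."""
    by_class: dict = {}
    for fs, sid in train_items:
        by_class.setdefault(sid, []).append(fs)
    models = {}
    for sid, seqs in by_class.items():
        motions = (SIL,) + protocol.motions_of_stroke(sid) + (SIL,)
        corpus = [(fs, motions) for fs in seqs]
        ms, _ = hmm.standard_training(corpus, sorted(set(motions)),
                                      n_components=n_components,
                                      iters_per_stage=iters)
        models[sid] = (ms, motions)
    preds = []
    for fs, _sid in test_items:
        scores = {sid: hmm.forward_loglik(ms, motions, fs)
                  for sid, (ms, motions) in models.items()}
        preds.append(max(sorted(scores), key=lambda s: scores[s]))
    return preds


def run_isolated_baseline(cfg: ExperimentConfig, protocol=None, profile=None):
    """10-fold cross-validated DTW vs HMM isolated stroke recognition."""
    protocol = protocol or default_protocol()
    profile = profile or default_profiles()[0]
    scfg = synth.SynthConfig(seed=cfg.seed + 7)
    items = _isolated_dataset(protocol, profile, scfg, cfg.isolated_reps)
    labels = [sid for _fs, sid in items]
    folds = metrics.kfold_split(list(range(len(items))), k=10, seed=cfg.seed,
                                labels=labels)
    dtw_true, dtw_pred, hmm_true, hmm_pred = [], [], [], []
    for fold in folds:
        test_idx = set(fold)
        train_items = [items[i] for i in range(len(items)) if i not in test_idx]
        test_items = [items[i] for i in sorted(test_idx)]
        templates = [dtw.Template(sid, fs.frames) for fs, sid in train_items]
        for fs, sid in test_items:
            dtw_true.append(sid)
            dtw_pred.append(dtw.classify_stroke(templates, fs.frames))
        preds = _hmm_isolated_classifier(train_items, test_items, protocol)
        hmm_true.extend(sid for _fs, sid in test_items)
        hmm_pred.extend(preds)
    _pc, dtw_macro = metrics.precision_recall_f1(
        metrics.ConfusionTally.from_pairs(dtw_true, dtw_pred))
    _pc, hmm_macro = metrics.precision_recall_f1(
        metrics.ConfusionTally.from_pairs(hmm_true, hmm_pred))
    return {"dtw": dtw_macro, "hmm": hmm_macro,
            "n_items": len(items)}


def run_continuous_user_dependent(cfg: ExperimentConfig, dataset=None,
                                  with_hybrid: bool = True):
    """User-dependent continuous recognition: GMM-HMM and hybrid CERs."""
    ds = dataset or build_continuous_dataset(cfg)
    out = {"per_user": {}, "input_rate_char_per_min": None}
    rates = []
    durations = []
    texts = []
    for prof in ds.profiles:
        ms = train_continuous_gmm(ds.train[prof.name], ds.protocol, cfg)
        graph = decoder.build_graph(ds.protocol, ms)
        cer_gmm, hyps = evaluate_cer(ds.test[prof.name], graph, ds.protocol,
                                     ds.lm, cfg.beam)
        row = {"cer_gmm": cer_gmm}
        if with_hybrid:
            hy = train_hybrid(ms, ds.train[prof.name], seed=cfg.seed)
            cer_dnn, _ = evaluate_cer(ds.test[prof.name], graph, ds.protocol,
                                      ds.lm, cfg.beam, hybrid=hy)
            row["cer_dnn"] = cer_dnn
        out["per_user"][prof.name] = row
        for _fs, text, dur in ds.test[prof.name]:
            durations.append(dur)
            texts.append(text)
    out["input_rate_char_per_min"] = metrics.input_rate(texts, durations)
    out["mean_cer_gmm"] = float(np.mean(
        [r["cer_gmm"] for r in out["per_user"].values()]))
    if with_hybrid:
        out["mean_cer_dnn"] = float(np.mean(
            [r["cer_dnn"] for r in out["per_user"].values()]))
    return out


def run_adaptation_sweep(cfg: ExperimentConfig, dataset=None):
    """User-independent baseline on a shifted user, then MLLR/MAP adaptation
    with growing amounts of that user's data."""
    ds = dataset or build_continuous_dataset(cfg)
    source, target = ds.profiles[0], ds.profiles[-1]
    ms_ui = train_continuous_gmm(ds.train[source.name], ds.protocol, cfg)
    graph_ui = decoder.build_graph(ds.protocol, ms_ui)
    cer_ui, _ = evaluate_cer(ds.test[target.name], graph_ui, ds.protocol,
                             ds.lm, cfg.beam)
    results = {"cer_user_independent": cer_ui, "map": {}, "mllr": {}}
    target_train = ds.train[target.name]
    for amount in cfg.adaptation_amounts:
        subset = target_train[:amount]
        stats = adapt_mod.accumulate_adaptation_stats(
            ms_ui, [(fs, motions) for fs, motions, _t in subset])
        ms_map = adapt_mod.map_update(ms_ui, stats, tau=10.0)
        cer_map, _ = evaluate_cer(ds.test[target.name],
                                  decoder.build_graph(ds.protocol, ms_map),
                                  ds.protocol, ds.lm, cfg.beam)
        results["map"][amount] = cer_map
    amount = cfg.adaptation_amounts[-1]
    stats = adapt_mod.accumulate_adaptation_stats(
        ms_ui, [(fs, motions) for fs, motions, _t in target_train[:amount]])
    try:
        ms_mllr = adapt_mod.mllr_update(ms_ui, stats)
        cer_mllr, _ = evaluate_cer(ds.test[target.name],
                                   decoder.build_graph(ds.protocol, ms_mllr),
                                   ds.protocol, ds.lm, cfg.beam)
        results["mllr"][amount] = cer_mllr
    except adapt_mod.InsufficientOccupancyError:
        results["mllr"][amount] = None
    return results


_EXPERIMENTS = {
    "isolated_baseline": run_isolated_baseline,
    "continuous_user_dependent": run_continuous_user_dependent,
    "adaptation_sweep": run_adaptation_sweep,
}


def run_experiment(name: str, cfg: ExperimentConfig | None = None) -> dict:
    """Run one of the canned experiments; returns its metrics dict."""
    if name not in _EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"choose from {sorted(_EXPERIMENTS)}")
    cfg = cfg or ExperimentConfig()
    t0 = time.time()
    result = _EXPERIMENTS[name](cfg)
    result["experiment"] = name
    result["seed"] = cfg.seed
    result["elapsed_s"] = round(time.time() - t0, 2)
    if cfg.output_dir:
        import json
        import os
        os.makedirs(cfg.output_dir, exist_ok=True)
        with open(os.path.join(cfg.output_dir, f"{name}.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(result, fh, indent=2, default=str)
    return result
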