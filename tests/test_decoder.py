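import itertools

import numpy as np
import pytest

from eyewrite import decoder, hmm, lm as lm_mod, synth
from eyewrite.decoder import BeamConfig, build_graph, decode, progressive_decode
from eyewrite.experiments import continuous_features
from eyewrite.protocol import SIL, Protocol, Stroke


def toy_protocol():
    """Two characters over single-motion strokes: A=up, B=down."""
    return Protocol(
        strokes={1: Stroke(1, ("up",)), 2: Stroke(2, ("down",))},
        lexicon={"A": (1,), "B": (2,)},
        sil_policy="both",
    )


def toy_model(sep=6.0, var=1.0):
    """Hand-set single-Gaussian units with well separated means."""
    units = {"up": (0.0, sep), "down": (0.0, -sep), SIL: (0.0, 0.0)}
    emissions = []
    unit_map = {}
    for name, mu in units.items():
        ids = np.arange(len(emissions), len(emissions) + hmm.N_STATES)
        for _k in range(hmm.N_STATES):
            emissions.append(hmm.GaussianMixtureState(
                np.array([1.0]), np.array([mu]), np.full((1, 2), var)))
        unit_map[name] = hmm.UnitHMM(name, ids, np.full(hmm.N_STATES, 0.5))
    return hmm.ModelSet(emissions=emissions, units=unit_map, dim=2,
                        var_floor=np.full(2, 1e-8),
                        global_mean=np.zeros(2), global_var=np.ones(2))


def clean_frames(protocol, ms, text, frames_per_state=2, rng=None):
    """Feature frames tracing the state means of the compiled chain."""
    chain = hmm.compile_chain(ms, protocol.compile_text(text))
    frames = []
    for j in range(chain.n_states):
        mu = ms.emissions[chain.emis_ids[j]].means[0]
        for _ in range(frames_per_state):
            frames.append(mu)
    X = np.array(frames)
    if rng is not None:
        X = X + rng.normal(0, 0.2, size=X.shape)
    return X


def oracle_best(protocol, ms, X, ngram, cfg, max_chars=2):
    """Exhaustive search over all character sequences up to max_chars."""
    chars = protocol.characters
    lmv = decoder._LMView(ngram, list(chars), cfg.lm_scale)
    best = (-np.inf, None)
    for n in range(0, max_chars + 1):
        for seq in itertools.product(chars, repeat=n):
            motions = protocol.compile_text(seq)
            chain = hmm.compile_chain(ms, motions)
            if chain.n_states > len(X):
                continue
            try:
                *_s, ll, _p, _c = hmm.viterbi_align(ms, motions, X)
            except hmm.InfeasibleAlignmentError:
                continue
            lm_total = 0.0
            hist = ()
            for c in seq:
                lm_total += lmv.vector(hist)[list(chars).index(c)]
                hist += (c,)
            lm_total += lmv.end(hist)
            total = ll + lm_total - cfg.insertion_penalty * n
            if total > best[0]:
                best = (total, seq)
    return best


class TestExhaustiveEquivalence:
    @pytest.mark.parametrize("text", ["A", "B", "AB", "BA", "AA"])
    def test_unbounded_beam_matches_oracle(self, rng, text):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, text, rng=rng)
        cfg = BeamConfig(beam=np.inf, max_active_contexts=10_000)
        ngram = lm_mod.train_ngram([["A"], ["B"], ["A", "B"], ["B", "A"]],
                                   order=2, vocab=["A", "B", lm_mod.EOS])
        res = decode(X, graph, p, ngram, cfg)
        expect_score, expect_seq = oracle_best(p, ms, X, ngram, cfg)
        assert res.characters.symbols == expect_seq
        assert res.score == pytest.approx(expect_score, abs=1e-6)

    def test_uniform_lm_oracle(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, "AB", rng=rng)
        cfg = BeamConfig(beam=np.inf, max_active_contexts=10_000)
        res = decode(X, graph, p, None, cfg)
        expect_score, expect_seq = oracle_best(p, ms, X, None, cfg)
        assert res.characters.symbols == expect_seq
        assert res.score == pytest.approx(expect_score, abs=1e-6)


class TestDecodeBehavior:
    def test_single_character_clean_signal(self, protocol, small_model):
        """A noiseless-ish rendering of one character decodes to itself
        (or a homograph resolved by the LM; use an unambiguous char)."""
        cfg = synth.SynthConfig(seed=40, noise_sigma_uv=2.0,
                                drift_sigma_uv=2.0)
        rec, _ = synth.render_motions(protocol.compile_text("ロ"),
                                      synth.UserProfile(name="t0", seed=1),
                                      cfg, item_seed=7)
        fs = continuous_features(rec)
        graph = build_graph(protocol, small_model)
        res = decode(fs, graph, protocol, None, BeamConfig())
        assert res.characters.symbols == ("ロ",)

    def test_score_decomposition(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        ngram = lm_mod.train_ngram([["A", "B"]], order=2,
                                   vocab=["A", "B", lm_mod.EOS])
        cfg = BeamConfig(lm_scale=1.7, insertion_penalty=0.4)
        X = clean_frames(p, ms, "AB", rng=rng)
        res = decode(X, graph, p, ngram, cfg)
        seq = res.characters.symbols
        lm_direct = cfg.lm_scale * ngram.logprob(seq)
        assert res.score == pytest.approx(
            res.acoustic_score + lm_direct
            - cfg.insertion_penalty * len(seq), abs=1e-6)
        assert res.lm_score == pytest.approx(lm_direct, abs=1e-6)

    def test_alignment_tiles_input(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, "AB", rng=rng)
        res = decode(X, graph, p, None, BeamConfig())
        assert res.unit_segments[0].start == 0
        assert res.unit_segments[-1].end == len(X)

    def test_raising_insertion_penalty_never_lengthens_output(self, rng):
        p = toy_protocol()
        ms = toy_model(sep=3.0)
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, "AAB", rng=rng)
        lengths = []
        for pen in (0.0, 5.0, 50.0, 500.0):
            cfg = BeamConfig(beam=np.inf, max_active_contexts=1000,
                             insertion_penalty=pen)
            res = decode(X, graph, p, None, cfg)
            lengths.append(len(res.characters.symbols))
        assert all(b <= a for a, b in zip(lengths, lengths[1:]))

    def test_no_complete_hypothesis_raises_named_error(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        # 2 frames cannot even traverse the 4-state leading sil chain
        X = rng.normal(size=(2, 2))
        with pytest.raises(decoder.EmptyBeamError):
            decode(X, graph, p, None, BeamConfig())

    def test_short_input_decodes_to_empty(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        # 6 frames fit the sil chain but no character sub-chain
        X = np.zeros((6, 2)) + rng.normal(0, 0.2, size=(6, 2))
        res = decode(X, graph, p, None, BeamConfig())
        assert res.characters.symbols == ()

    def test_ambiguous_characters_resolved_by_lm(self, protocol, small_model):
        """キ and チ share one expansion; the LM picks the likelier one."""
        groups = [g for g in protocol.ambiguous_groups() if "キ" in g]
        assert groups and "チ" in groups[0]
        cfg = synth.SynthConfig(seed=41, noise_sigma_uv=2.0)
        rec, _ = synth.render_motions(protocol.compile_text("キ"),
                                      synth.UserProfile(name="t0", seed=1),
                                      cfg, item_seed=3)
        fs = continuous_features(rec)
        graph = build_graph(protocol, small_model)
        vocab = list(protocol.characters) + [lm_mod.EOS]
        lm_ki = lm_mod.train_ngram([["キ"]] * 5, order=2, vocab=vocab)
        lm_chi = lm_mod.train_ngram([["チ"]] * 5, order=2, vocab=vocab)
        r1 = decode(fs, graph, protocol, lm_ki, BeamConfig())
        r2 = decode(fs, graph, protocol, lm_chi, BeamConfig())
        assert r1.characters.symbols == ("キ",)
        assert r2.characters.symbols == ("チ",)


class TestProgressive:
    def test_threshold_zero_matches_batch(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        ngram = lm_mod.train_ngram([["A", "B"], ["B"]], order=2,
                                   vocab=["A", "B", lm_mod.EOS])
        for text in ("AB", "BA", "A"):
            X = clean_frames(p, ms, text, rng=rng)
            cfg = BeamConfig(progressive_threshold=0.0)
            batch = decode(X, graph, p, ngram, cfg)
            prog = progressive_decode(X, graph, p, ngram, cfg)
            assert prog.characters.symbols == batch.characters.symbols
            assert prog.score == pytest.approx(batch.score, abs=1e-9)

    def test_commits_cover_output_and_are_ordered(self, rng):
        p = toy_protocol()
        ms = toy_model()
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, "AB", frames_per_state=3, rng=rng)
        cfg = BeamConfig(progressive_threshold=1e-3)
        res = progressive_decode(X, graph, p, None, cfg)
        assert tuple(c for _t, c in res.commits) == res.characters.symbols
        times = [t for t, _c in res.commits]
        assert times == sorted(times)

    def test_ambiguous_prefix_defers_commitment(self, rng):
        """Two characters sharing a long prefix: the first character cannot
        commit until the disambiguating motion arrives."""
        p = Protocol(
            strokes={1: Stroke(1, ("up", "right", "down")),
                     2: Stroke(2, ("up", "right", "up"))},
            lexicon={"A": (1,), "B": (2,)},
            sil_policy="both",
        )
        units = {"up": (0.0, 6.0), "down": (0.0, -6.0), "right": (6.0, 0.0),
                 SIL: (0.0, 0.0)}
        emissions = []
        unit_map = {}
        for name, mu in units.items():
            ids = np.arange(len(emissions), len(emissions) + hmm.N_STATES)
            for _k in range(hmm.N_STATES):
                emissions.append(hmm.GaussianMixtureState(
                    np.array([1.0]), np.array([mu]), np.full((1, 2), 1.0)))
            unit_map[name] = hmm.UnitHMM(name, ids, np.full(hmm.N_STATES, 0.5))
        ms = hmm.ModelSet(emissions=emissions, units=unit_map, dim=2,
                          var_floor=np.full(2, 1e-8),
                          global_mean=np.zeros(2), global_var=np.ones(2))
        graph = build_graph(p, ms)
        X = clean_frames(p, ms, "A", frames_per_state=3, rng=rng)
        res = progressive_decode(X, graph, p, None,
                                 BeamConfig(progressive_threshold=1e-3))
        assert res.characters.symbols == ("A",)
        (t_commit, _c) = res.commits[0]
        # up+right span: sil(4) + up(4) + right(4) states, 3 frames each
        frames_before_down = 3 * (4 + 4 + 4)
        assert t_commit >= frames_before_down - 3
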