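import numpy as np
import pytest

from eyewrite import synth
from eyewrite.experiments import continuous_features
from eyewrite.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def synth_cfg():
    return synth.SynthConfig(seed=123)


@pytest.fixture(scope="session")
def small_corpus(protocol, synth_cfg):
    """20 synthetic words x 2 reps, featurized for the continuous path."""
    words = synth.make_word_list(protocol, 20, seed=3)
    items = synth.generate_corpus(words, protocol,
                                  synth.UserProfile(name="t0", seed=1),
                                  synth_cfg, n_reps=2)
    return [(continuous_features(it["recording"]), it["motions"], it["text"])
            for it in items]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_model(protocol, small_corpus):
    """A small GMM-HMM trained on the shared word corpus."""
    from eyewrite import hmm
    corpus = [(fs, m) for fs, m, _t in small_corpus]
    ms, _hist = hmm.standard_training(corpus, protocol.motion_alphabet(),
                                      n_components=2, iters_per_stage=3)
    return ms
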