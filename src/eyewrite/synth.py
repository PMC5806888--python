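"""Seeded synthetic two-channel EOG generator.

The simulator renders labelled 1 kHz EOG from any character text under any
protocol.  The gaze is modelled as a piecewise-constant target position in
"unit steps" (one step per directional motion, diagonals at +-45 degrees)
reached through smooth sigmoid transitions of saccade-like duration; the
``sil`` unit returns the gaze to the neutral position and holds it there,
which matches its role as "no motion at neutral" and keeps the rendered
deflections inside the physiological 250-1000 uV band.  Position is mapped
to microvolts with a soft saturation at +-1000 uV.

On top of the clean path the simulator adds the artifact families seen in
real recordings: baseline drift (integrated white noise), powerline
interference, white sensor noise, and biphasic blink spikes on the
vertical channel.  Per-user variability (channel gains, writing speed,
electrode crosstalk, drift level) is expressed through ``UserProfile``.
All randomness flows from an explicit (corpus seed -> user seed -> item
seed) hierarchy, so every dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EOGRecording, LabelSegment, Transcription
from .protocol import BLINK, SIL, Protocol

__all__ = [
    "SynthConfig",
    "UserProfile",
    "render_motions",
    "generate_corpus",
    "spectral_check",
    "make_word_list",
    "make_sentences",
    "sample_text",
]

# unit displacement per directional motion, in gaze steps
_DIAG = 1.0 / np.sqrt(2.0)
_DISPLACEMENT = {
    "up": (0.0, 1.0),
    "down": (0.0, -1.0),
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
    "upper_left": (-_DIAG, _DIAG),
    "upper_right": (_DIAG, _DIAG),
    "lower_left": (-_DIAG, -_DIAG),
    "lower_right": (_DIAG, -_DIAG),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the simulator (amplitudes in uV, durations in s)."""

    sample_rate_hz: float = 1000.0
    amplitude_uv: float = 600.0        # deflection per unit gaze step
    saturation_uv: float = 1000.0      # soft physiological ceiling
    saccade_s: float = 0.15            # transition duration
    hold_s: float = 0.35               # mean hold per motion
    hold_jitter_s: float = 0.05        # uniform +- jitter on holds
    blink_amplitude_uv: float = 400.0
    blink_s: float = 0.25
    noise_sigma_uv: float = 8.0        # white sensor noise
    drift_sigma_uv: float = 20.0       # random-walk scale per sqrt(second)
    powerline_uv: float = 5.0
    powerline_hz: float = 50.0
    seed: int = 0


@dataclass(frozen=True)
class UserProfile:
    """Per-user rendering variability."""

    name: str = "user"
    h_scale: float = 1.0
    v_scale: float = 1.0
    speed_scale: float = 1.0           # >1 writes faster (shorter durations)
    crosstalk_deg: float = 0.0         # electrode-axis rotation
    drift_scale: float = 1.0
    seed: int = 0


def _sigmoid_step(n: int) -> np.ndarray:
    """Smooth 0->1 transition of n samples (logistic, clipped tails)."""
    t = np.linspace(-6.0, 6.0, n)
    return 1.0 / (1.0 + np.exp(-t))


def render_motions(motions, profile: UserProfile | None = None,
                   cfg: SynthConfig | None = None, *, item_seed: int = 0):
    """Render a motion-unit sequence to (EOGRecording, gold LabelSegments).

    The returned segments tile the recording exactly, one per input motion
    (transition plus hold).  Deterministic under (cfg.seed, profile.seed,
    item_seed).
    """
    if not motions:
        raise ValueError("empty motion sequence")
    cfg = cfg or SynthConfig()
    profile = profile or UserProfile()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF,
                                 profile.seed & 0x7FFFFFFF,
                                 item_seed & 0x7FFFFFFF])
    fs = cfg.sample_rate_hz
    speed = profile.speed_scale

    pos = np.zeros(2)
    h_parts, v_parts = [], []
    segments = []
    blink_events = []  # (center_sample, duration_samples)
    cursor = 0
    for m in motions:
        jitter = rng.uniform(-cfg.hold_jitter_s, cfg.hold_jitter_s)
        hold_n = max(1, int(round((cfg.hold_s + jitter) / speed * fs)))
        trans_n = max(1, int(round(cfg.saccade_s / speed * fs)))
        if m == SIL:
            target = np.zeros(2)
        elif m == BLINK:
            target = pos
            blink_events.append((cursor + trans_n // 2,
                                 max(4, int(round(cfg.blink_s / speed * fs)))))
        elif m == "center_return":
            target = np.zeros(2)
        elif m in _DISPLACEMENT:
            target = pos + np.asarray(_DISPLACEMENT[m])
        else:
            raise ValueError(f"unknown motion unit {m!r}")
        step = _sigmoid_step(trans_n)
        h_parts.append(pos[0] + (target[0] - pos[0]) * step)
        v_parts.append(pos[1] + (target[1] - pos[1]) * step)
        h_parts.append(np.full(hold_n, target[0]))
        v_parts.append(np.full(hold_n, target[1]))
        seg_len = trans_n + hold_n
        segments.append(LabelSegment(cursor, cursor + seg_len, m))
        cursor += seg_len
        pos = target

    h = np.concatenate(h_parts) * cfg.amplitude_uv
    v = np.concatenate(v_parts) * cfg.amplitude_uv
    n = len(h)
    t = np.arange(n) / fs

    # blink spikes: biphasic bump on the vertical channel
    for center, dur in blink_events:
        w = dur / 4.0
        bump = cfg.blink_amplitude_uv * (
            np.exp(-0.5 * ((np.arange(n) - center) / w) ** 2)
            - 0.4 * np.exp(-0.5 * ((np.arange(n) - center - 1.2 * w) / w) ** 2)
        )
        v = v + bump

    # soft physiological saturation
    sat = cfg.saturation_uv
    h = sat * np.tanh(h / sat)
    v = sat * np.tanh(v / sat)

    # electrode crosstalk then per-channel gain
    theta = np.deg2rad(profile.crosstalk_deg)
    if theta != 0.0:
        h, v = (np.cos(theta) * h - np.sin(theta) * v,
                np.sin(theta) * h + np.cos(theta) * v)
    h = h * profile.h_scale
    v = v * profile.v_scale

    # artifacts: random-walk drift, powerline, white noise
    step_sd = cfg.drift_sigma_uv * profile.drift_scale / np.sqrt(fs)
    h = h + np.cumsum(rng.normal(0.0, step_sd, n))
    v = v + np.cumsum(rng.normal(0.0, step_sd, n))
    phase_h, phase_v = rng.uniform(0.0, 2 * np.pi, 2)
    h = h + cfg.powerline_uv * np.sin(2 * np.pi * cfg.powerline_hz * t + phase_h)
    v = v + cfg.powerline_uv * np.sin(2 * np.pi * cfg.powerline_hz * t + phase_v)
    h = h + rng.normal(0.0, cfg.noise_sigma_uv, n)
    v = v + rng.normal(0.0, cfg.noise_sigma_uv, n)

    h = np.clip(h, -sat, sat)
    v = np.clip(v, -sat, sat)

    rec = EOGRecording(sample_rate_hz=fs, horizontal=h, vertical=v,
                       meta={"user": profile.name, "seed": str(item_seed)})
    return rec, segments


def generate_corpus(texts, protocol: Protocol, profiles, cfg: SynthConfig,
                    n_reps: int = 1) -> list:
    """Render one labelled item per (text, repetition, user profile).

    Returns a list of dicts with keys ``recording``, ``text``,
    ``transcription``, ``segments``, ``motions``, ``user`` and ``rep``.
    """
    if isinstance(profiles, UserProfile):
        profiles = [profiles]
    items = []
    for profile in profiles:
        for rep in range(n_reps):
            for i, text in enumerate(texts):
                motions = protocol.compile_text(text)
                rec, segs = render_motions(
                    motions, profile, cfg,
                    item_seed=(rep * 1_000_003 + i) & 0x7FFFFFFF)
                items.append({
                    "recording": rec,
                    "text": text,
                    "transcription": Transcription(tuple(text), tier="character"),
                    "segments": segs,
                    "motions": motions,
                    "user": profile.name,
                    "rep": rep,
                })
    return items


def spectral_check(rec: EOGRecording, *, band_hz: float = 30.0,
                   powerline_hz: float = 50.0, notch_hz: float = 2.0) -> dict:
    """Report the fraction of signal power below ``band_hz``.

    Bins within ``notch_hz`` of the powerline frequency are excluded from
    the total, so injected interference does not count against the
    physiological band.
    """
    x = rec.as_array()
    f, p = sps.periodogram(x, fs=rec.sample_rate_hz, axis=0)
    p = p.sum(axis=1)
    keep = np.abs(f - powerline_hz) > notch_hz
    total = p[keep].sum()
    low = p[keep & (f < band_hz)].sum()
    return {
        "fraction_below_band": float(low / total) if total > 0 else 1.0,
        "band_hz": band_hz,
        "powerline_bin_power": float(p[~keep].sum()),
        "total_power": float(total),
    }


# ---------------------------------------------------------------------------
# text sampling (word lists, sentences, LM corpora)

def _char_weights(protocol: Protocol, rng) -> tuple:
    """Zipf-like character frequencies in a seeded random rank order."""
    chars = list(protocol.characters)
    rng.shuffle(chars)
    w = np.array([1.0 / (r + 2.0) for r in range(len(chars))])
    return chars, w / w.sum()


def make_word_list(protocol: Protocol, n_words: int = 150, seed: int = 0,
                   lengths=(1, 2, 3), length_probs=(0.05, 0.15, 0.80)) -> list:
    """Sample a distinct word list (default sizing: 150 words of 1-3
    characters, mean length near 2.8)."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    chars, w = _char_weights(protocol, rng)
    words: list = []
    seen = set()
    guard = 0
    while len(words) < n_words:
        guard += 1
        if guard > 100 * n_words:
            raise RuntimeError("could not sample enough distinct words")
        k = rng.choice(lengths, p=length_probs)
        word = "".join(rng.choice(chars, size=k, p=w))
        if word not in seen:
            seen.add(word)
            words.append(word)
    return words


def make_sentences(words, n_sentences: int = 25, seed: int = 0,
                   min_chars: int = 5, max_chars: int = 20) -> list:
    """Concatenate words into sentences of bounded character length."""
    rng = np.random.default_rng((seed + 1) & 0x7FFFFFFF)
    sentences = []
    for _ in range(n_sentences):
        target = rng.integers(min_chars, max_chars + 1)
        s = ""
        while len(s) < target:
            s += words[rng.integers(len(words))]
        sentences.append(s[:max_chars])
    return sentences


def sample_text(words, n_sentences: int, seed: int = 0,
                words_per_sentence=(2, 8), exclude=()) -> list:
    """Sample a word-concatenation text corpus (for LM training), skipping
    any sentence string listed in ``exclude``."""
    rng = np.random.default_rng((seed + 2) & 0x7FFFFFFF)
    excluded = set(exclude)
    out = []
    guard = 0
    while len(out) < n_sentences:
        guard += 1
        if guard > 50 * n_sentences + 100:
            break
        k = rng.integers(words_per_sentence[0], words_per_sentence[1] + 1)
        s = "".join(words[rng.integers(len(words))] for _ in range(k))
        if s not in excluded:
            out.append(s)
    return out
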