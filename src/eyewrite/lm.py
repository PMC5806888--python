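"""Backoff character N-gram language model.

Training uses interpolated Witten-Bell smoothing, expressed in standard
backoff form so models round-trip through the ARPA text format.  The
vocabulary is fixed at construction (the 70 protocol characters plus
sentence-boundary symbols); every conditional distribution is properly
normalized over the prediction vocabulary, and unseen histories back off
with the usual backoff-weight correction.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

__all__ = ["BOS", "EOS", "NGramModel", "train_ngram", "read_arpa", "write_arpa"]

BOS = "<s>"
EOS = "</s>"

_LOG10 = math.log(10.0)
_MIN_LOGPROB = -99.0 * _LOG10  # ARPA convention for "effectively zero"


@dataclass
class NGramModel:
    """Backoff N-gram over a fixed symbol vocabulary.

    ``table[k]`` maps a k-gram tuple to ``[logprob, backoff]`` (natural
    logs); backoff is only meaningful for tuples that occur as contexts.
    """

    order: int
    vocab: tuple                      # prediction vocabulary (includes EOS, not BOS)
    table: dict = field(default_factory=dict)   # k -> {tuple: [logp, bow]}
    oov_mode: str = "strict"          # "strict" | "floor"
    _vec_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vocab = tuple(self.vocab)
        if BOS in self.vocab:
            raise ValueError("BOS is never predicted and must not be in vocab")

    # -- scoring ----------------------------------------------------------

    def cond_logprob(self, symbol: str, context=()) -> float:
        """log P(symbol | context), context truncated to the last N-1 symbols."""
        if symbol not in self._vocab_set:
            if self.oov_mode == "floor":
                return _MIN_LOGPROB
            raise KeyError(f"out-of-vocabulary symbol {symbol!r}")
        h = tuple(context)[-(self.order - 1):] if self.order > 1 else ()
        return self._lp(symbol, h)

    @property
    def _vocab_set(self):
        vs = getattr(self, "_vset", None)
        if vs is None:
            vs = self._vset = set(self.vocab)
        return vs

    def _lp(self, w: str, h: tuple) -> float:
        entry = self.table.get(len(h) + 1, {}).get(h + (w,))
        if entry is not None:
            return entry[0]
        if not h:
            return _MIN_LOGPROB
        ctx = self.table.get(len(h), {}).get(h)
        bow = ctx[1] if ctx is not None else 0.0
        return bow + self._lp(w, h[1:])

    def logprob_vector(self, context=()):
        """Tuple of cond_logprob over the whole vocabulary (cached per
        truncated context) — the decoder's fast path."""
        h = tuple(context)[-(self.order - 1):] if self.order > 1 else ()
        vec = self._vec_cache.get(h)
        if vec is None:
            vec = tuple(self._lp(w, h) for w in self.vocab)
            self._vec_cache[h] = vec
        return vec

    def logprob(self, symbols, *, bounds: bool = True) -> float:
        """Total log probability of a symbol sequence.

        With ``bounds`` (default) the sequence is scored as a sentence:
        a BOS context is prepended and an EOS event appended.
        """
        history = [BOS] if bounds else []
        total = 0.0
        for s in symbols:
            total += self.cond_logprob(s, history)
            history.append(s)
        if bounds:
            total += self.cond_logprob(EOS, history)
        return total

    def perplexity(self, sentences) -> float:
        total, n = 0.0, 0
        for sent in sentences:
            total += self.logprob(sent)
            n += len(sent) + 1  # + EOS event
        return math.exp(-total / max(n, 1))


def train_ngram(corpus, order: int = 5, vocab=None,
                smoothing: str = "witten-bell") -> NGramModel:
    """Train a Witten-Bell backoff N-gram from symbol sequences.

    ``corpus`` is an iterable of sentences (each an iterable of symbols).
    ``vocab`` fixes the prediction vocabulary; by default it is the set of
    corpus symbols plus EOS.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if smoothing != "witten-bell":
        raise ValueError(f"unsupported smoothing {smoothing!r}")
    sentences = [list(s) for s in corpus]
    if not sentences:
        raise ValueError("empty corpus")
    if vocab is None:
        vocab = sorted({w for s in sentences for w in s}) + [EOS]
    vocab = tuple(vocab)
    vset = set(vocab)
    for s in sentences:
        for w in s:
            if w not in vset:
                raise KeyError(f"corpus symbol {w!r} not in vocabulary")

    # n-gram counts; BOS only ever appears in contexts
    counts = [defaultdict(int) for _ in range(order + 1)]
    for s in sentences:
        toks = [BOS] + s + [EOS]
        for i in range(1, len(toks)):
            for k in range(1, order + 1):
                if i - (k - 1) < 0:
                    continue
                counts[k][tuple(toks[i - k + 1:i + 1])] += 1

    ctx_total = [defaultdict(int) for _ in range(order)]
    ctx_types = [defaultdict(int) for _ in range(order)]
    for k in range(1, order + 1):
        for gram, c in counts[k].items():
            ctx_total[k - 1][gram[:-1]] += c
            ctx_types[k - 1][gram[:-1]] += 1

    V = len(vocab)
    memo: dict = {}

    def p_wb(w: str, h: tuple) -> float:
        key = h + (w,)
        got = memo.get(key)
        if got is not None:
            return got
        k = len(h)
        c = counts[k + 1].get(key, 0)
        tot = ctx_total[k].get(h, 0)
        types = ctx_types[k].get(h, 0)
        if not h:
            lower = 1.0 / V
        else:
            lower = p_wb(w, h[1:])
        if tot + types == 0:
            p = lower
        else:
            lam = types / (tot + types)
            p = c / (tot + types) + lam * lower
        memo[key] = p
        return p

    table: dict = {k: {} for k in range(1, order + 1)}
    # probabilities for every seen n-gram; all vocab unigrams are listed
    for w in vocab:
        table[1][(w,)] = [math.log(max(p_wb(w, ()), 1e-300)), 0.0]
    for k in range(2, order + 1):
        for gram in counts[k]:
            h, w = gram[:-1], gram[-1]
            if w == BOS:
                continue
            table[k][gram] = [math.log(max(p_wb(w, h), 1e-300)), 0.0]

    # backoff weights for contexts of orders 1..N-1
    for k in range(1, order):
        for h in ctx_total[k]:
            seen = [w for w in vocab if h + (w,) in table[k + 1]]
            num = 1.0 - sum(math.exp(table[k + 1][h + (w,)][0]) for w in seen)
            den = 1.0 - sum(math.exp(_lookup(table, w, h[1:])) for w in seen)
            if num <= 1e-12:
                bow = _MIN_LOGPROB
            elif den <= 1e-12:
                bow = 0.0
            else:
                bow = math.log(num / den)
            entry = table[len(h)].setdefault(h, [_MIN_LOGPROB, 0.0])
            entry[1] = bow
    return NGramModel(order=order, vocab=vocab, table=table)


def _lookup(table, w, h):
    entry = table.get(len(h) + 1, {}).get(tuple(h) + (w,))
    if entry is not None:
        return entry[0]
    if not h:
        return _MIN_LOGPROB
    ctx = table.get(len(h), {}).get(tuple(h))
    bow = ctx[1] if ctx is not None else 0.0
    return bow + _lookup(table, w, h[1:])


# ---------------------------------------------------------------------------
# ARPA interchange

def write_arpa(model: NGramModel, path) -> None:
    """Write the model in the standard ARPA text layout (log10 scores)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k in range(1, model.order + 1):
            fh.write(f"ngram {k}={len(model.table.get(k, {}))}\n")
        for k in range(1, model.order + 1):
            fh.write(f"\n\\{k}-grams:\n")
            for gram in sorted(model.table.get(k, {})):
                logp, bow = model.table[k][gram]
                line = f"{logp / _LOG10:.6f}\t{' '.join(gram)}"
                if k < model.order and bow != 0.0:
                    line += f"\t{bow / _LOG10:.6f}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


def read_arpa(path, oov_mode: str = "strict") -> NGramModel:
    """Read an ARPA-format backoff model."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines) and lines[i].strip() != "\\data\\":
        if lines[i].strip() and not lines[i].startswith("#"):
            raise ValueError(f"{path}: expected \\data\\ header, got {lines[i]!r}")
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: missing \\data\\ header")
    i += 1
    declared = {}
    while i < len(lines) and lines[i].strip().startswith("ngram"):
        decl = lines[i].split()[1]
        k, _, n = decl.partition("=")
        declared[int(k)] = int(n)
        i += 1
    if not declared:
        raise ValueError(f"{path}: no ngram count declarations")
    order = max(declared)
    table: dict = {k: {} for k in range(1, order + 1)}
    vocab = []
    current = None
    for ln in lines[i:]:
        s = ln.strip()
        if not s:
            continue
        if s == "\\end\\":
            current = None
            continue
        if s.startswith("\\") and s.endswith("-grams:"):
            current = int(s[1:].split("-")[0])
            continue
        if current is None:
            raise ValueError(f"{path}: stray line outside a section: {s!r}")
        parts = s.split("\t") if "\t" in s else s.split()
        logp = float(parts[0]) * _LOG10
        if len(parts) >= 3 and current < order:
            gram = tuple(parts[1].split()) if "\t" in s else tuple(parts[1:-1])
            bow = float(parts[-1]) * _LOG10
        else:
            gram = tuple(parts[1].split()) if "\t" in s else tuple(parts[1:])
            bow = 0.0
        if len(gram) != current:
            raise ValueError(f"{path}: {len(gram)}-gram in \\{current}-grams: section")
        table[current][gram] = [logp, bow]
        if current == 1 and gram[0] not in (BOS,):
            vocab.append(gram[0])
    return NGramModel(order=order, vocab=tuple(vocab), table=table,
                      oov_mode=oov_mode)
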