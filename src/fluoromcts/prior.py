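"""SMILES tokenizer, corpus vocabulary, and autoregressive token priors.

The search consumes the prior through a narrow contract: a conditional
next-token distribution over the vocabulary given a token prefix, and a
seeded sampler of sequence completions.  Two implementations are provided:

* :class:`RecurrentPrior` — a single-layer Elman recurrent network over
  learned token embeddings, trained with Adam on truncated-BPTT gradients.
  This is the default prior for real runs.
* :class:`NGramPrior` — a deterministic interpolated n-gram model used when
  training speed matters more than sample quality (the search core is
  agnostic to prior quality).

A :class:`UniformPrior` (no training) is also available for controlled
experiments on tiny grammars.
"""

from __future__ import annotations

import json
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError, VocabularyError

BEGIN_TOKEN = "^"
END_TOKEN = "$"

# Longest-match token pattern: bracket atoms, two-letter halogens, two-digit
# ring closures, then any single character.  Halogens tokenize correctly even
# though the default element filter downstream rejects them, so arbitrary
# corpora load.
_TOKEN_RE = re.compile(r"\[[^\]]+\]|Cl|Br|%\d{2}|.")


def split_smiles(text: str) -> list[str]:
    """Split a SMILES string into tokens (vocabulary-free)."""
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token alphabet plus sequence delimiters.

    The vocabulary is exactly the token set observed in the training corpus
    plus the begin/end markers; begin is never emitted inside a sequence.
    """

    tokens: tuple[str, ...]
    begin_token: str = BEGIN_TOKEN
    end_token: str = END_TOKEN

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise InputError("vocabulary tokens must be unique")
        if self.begin_token not in self.tokens or self.end_token not in self.tokens:
            raise InputError("vocabulary must contain begin and end tokens")

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "TokenVocabulary":
        seen: set[str] = set()
        for s in corpus:
            seen.update(split_smiles(s))
        ordered = sorted(seen)
        return cls(tokens=(BEGIN_TOKEN, END_TOKEN, *ordered))

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self._index_map[token]
        except KeyError:
            raise VocabularyError(f"unknown token {token!r}") from None

    @property
    def _index_map(self) -> dict[str, int]:
        # cached on the instance despite frozen dataclass
        m = self.__dict__.get("_imap")
        if m is None:
            m = {t: i for i, t in enumerate(self.tokens)}
            self.__dict__["_imap"] = m
        return m

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.int64)


def tokenize(text: str, vocab: TokenVocabulary) -> list[str]:
    """Tokenize ``text`` against ``vocab``; unknown tokens raise
    :class:`VocabularyError`.  Concatenating the result reproduces ``text``."""
    tokens = split_smiles(text)
    for t in tokens:
        if t not in vocab._index_map:
            raise VocabularyError(f"token {t!r} not in vocabulary")
    return tokens


def detokenize(tokens: list[str]) -> str:
    """Inverse of :func:`tokenize`: strip delimiters, concatenate the rest."""
    return "".join(t for t in tokens if t not in (BEGIN_TOKEN, END_TOKEN))


@dataclass(frozen=True)
class Completion:
    """Result of autoregressive sampling: the full token sequence, the
    detokenized SMILES text, and whether the end token was reached."""

    tokens: tuple[str, ...]
    text: str
    terminated: bool


class PriorModel(ABC):
    """Contract consumed by the search: conditional distribution + sampler."""

    vocab: TokenVocabulary
    metadata: dict

    @abstractmethod
    def next_token_distribution(self, prefix: list[str]) -> np.ndarray:
        """Probability vector over the vocabulary given ``prefix``.

        Deterministic given model and prefix; sums to 1 within 1e-9; the
        begin token always has probability 0.
        """

    def sample_completion(
        self, prefix: list[str], max_len: int, rng: np.random.Generator | int
    ) -> Completion:
        """Sample autoregressively from ``prefix`` until the end token or
        ``max_len`` total tokens; reproducible under a fixed seed.

        Hitting ``max_len`` without an end token returns the truncated
        sequence flagged unterminated.
        """
        if max_len < len(prefix):
            raise InputError("max_len must be at least the prefix length")
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        tokens = list(prefix)
        if tokens and tokens[-1] == self.vocab.end_token:
            return Completion(tuple(tokens), detokenize(tokens), True)
        while len(tokens) < max_len:
            p = self.next_token_distribution(tokens)
            idx = rng.choice(len(p), p=p)
            tok = self.vocab.tokens[idx]
            tokens.append(tok)
            if tok == self.vocab.end_token:
                return Completion(tuple(tokens), detokenize(tokens), True)
        return Completion(tuple(tokens), detokenize(tokens), False)

    def avg_nll(self, corpus: list[str]) -> float:
        """Average per-token negative log-likelihood of a corpus."""
        total, count = 0.0, 0
        for s in corpus:
            seq = [self.vocab.begin_token, *tokenize(s, self.vocab), self.vocab.end_token]
            for i in range(1, len(seq)):
                p = self.next_token_distribution(seq[:i])
                total -= float(np.log(max(p[self.vocab.index(seq[i])], 1e-300)))
                count += 1
        return total / max(count, 1)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a self-describing checkpoint archive (.npz)."""
        arrays = self._state_arrays()
        header = {
            "kind": type(self).__name__,
            "tokens": list(self.vocab.tokens),
            "metadata": self.metadata,
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path: str | Path) -> "PriorModel":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__header__"}
        vocab = TokenVocabulary(tokens=tuple(header["tokens"]))
        cls = {"RecurrentPrior": RecurrentPrior,
               "NGramPrior": NGramPrior,
               "UniformPrior": UniformPrior}[header["kind"]]
        return cls._from_state(vocab, header["metadata"], arrays)

    @abstractmethod
    def _state_arrays(self) -> dict[str, np.ndarray]: ...

    @classmethod
    @abstractmethod
    def _from_state(cls, vocab, metadata, arrays) -> "PriorModel": ...


class UniformPrior(PriorModel):
    """Maximum-entropy prior: every non-begin token equally likely."""

    def __init__(self, vocab: TokenVocabulary):
        self.vocab = vocab
        self.metadata = {"corpus_size": 0, "epochs": 0, "seed": None}

    def next_token_distribution(self, prefix: list[str]) -> np.ndarray:
        for t in prefix:
            self.vocab.index(t)
        p = np.ones(self.vocab.size)
        p[self.vocab.index(self.vocab.begin_token)] = 0.0
        return p / p.sum()

    def _state_arrays(self) -> dict[str, np.ndarray]:
        return {}

    @classmethod
    def _from_state(cls, vocab, metadata, arrays):
        m = cls(vocab)
        m.metadata = metadata
        return m


class NGramPrior(PriorModel):
    """Interpolated n-gram model with uniform back-off.

    P(t | ctx) is built bottom-up: starting from the uniform distribution,
    each observed context of increasing order k mixes in its maximum-
    likelihood distribution with weight ``lam``.  The result is a proper
    distribution at every prefix, never assigns zero mass, and is fully
    deterministic given the corpus.
    """

    def __init__(self, vocab: TokenVocabulary, order: int = 3, lam: float = 0.8):
        if order < 1:
            raise InputError("order must be >= 1")
        self.vocab = vocab
        self.order = order
        self.lam = lam
        # counts[k][context tuple] = count vector over vocab
        self.counts: list[dict[tuple[int, ...], np.ndarray]] = [
            {} for _ in range(order)
        ]
        self.metadata = {"corpus_size": 0, "epochs": 0, "seed": None,
                         "order": order, "lam": lam}

    def fit(self, corpus: list[str]) -> "NGramPrior":
        if not corpus:
            raise InputError("empty corpus")
        for s in corpus:
            seq = self.vocab.encode(
                [self.vocab.begin_token, *tokenize(s, self.vocab), self.vocab.end_token]
            )
            for i in range(1, len(seq)):
                target = seq[i]
                for k in range(self.order):
                    if i - 1 - k < 0:  # prefix shorter than context order
                        break
                    ctx = tuple(seq[i - 1 - k:i])
                    vec = self.counts[k].setdefault(
                        ctx, np.zeros(self.vocab.size))
                    vec[target] += 1
        self.metadata["corpus_size"] = len(corpus)
        return self

    def next_token_distribution(self, prefix: list[str]) -> np.ndarray:
        idx = [self.vocab.index(t) for t in prefix]
        p = np.ones(self.vocab.size)
        p[self.vocab.index(self.vocab.begin_token)] = 0.0
        p /= p.sum()
        for k in range(self.order):
            if len(idx) < k + 1:
                break
            ctx = tuple(idx[len(idx) - 1 - k:])
            vec = self.counts[k].get(ctx)
            if vec is not None and vec.sum() > 0:
                p = (1.0 - self.lam) * p + self.lam * (vec / vec.sum())
        return p

    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for k, table in enumerate(self.counts):
            if not table:
                continue
            ctxs = sorted(table)
            arrays[f"ctx{k}"] = np.array(
                [list(c) for c in ctxs], dtype=np.int64).reshape(len(ctxs), k + 1)
            arrays[f"cnt{k}"] = np.stack([table[c] for c in ctxs])
        return arrays

    @classmethod
    def _from_state(cls, vocab, metadata, arrays):
        m = cls(vocab, order=metadata["order"], lam=metadata["lam"])
        m.metadata = metadata
        for k in range(m.order):
            if f"ctx{k}" in arrays:
                for ctx_row, cnt_row in zip(arrays[f"ctx{k}"], arrays[f"cnt{k}"]):
                    m.counts[k][tuple(int(i) for i in ctx_row)] = cnt_row.astype(float)
        return m


class RecurrentPrior(PriorModel):
    """Single-layer Elman RNN over token embeddings, trained with Adam.

    h_t = tanh(E[x_t] Wxh + h_{t-1} Whh + bh);  logits = h_t Why + by.
    The begin-token logit is masked to -inf so begin is never emitted.
    Dense enough to fit small corpora in seconds on one CPU; the search
    treats it as an opaque conditional distribution.
    """

    def __init__(self, vocab: TokenVocabulary, embed_dim: int = 16,
                 hidden_dim: int = 32, seed: int = 0):
        self.vocab = vocab
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        rng = np.random.default_rng(seed)
        v = vocab.size
        s = 0.1
        self.params = {
            "E": rng.normal(0, s, (v, embed_dim)),
            "Wxh": rng.normal(0, s, (embed_dim, hidden_dim)),
            "Whh": rng.normal(0, s, (hidden_dim, hidden_dim)),
            "bh": np.zeros(hidden_dim),
            "Why": rng.normal(0, s, (hidden_dim, v)),
            "by": np.zeros(v),
        }
        self.metadata = {"corpus_size": 0, "epochs": 0, "seed": seed,
                         "embed_dim": embed_dim, "hidden_dim": hidden_dim}
        self._adam_m = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_v = {k: np.zeros_like(p) for k, p in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _forward(self, seq: np.ndarray):
        """Run the RNN over input tokens seq[:-1]; return hidden states and
        softmax probabilities for each position."""
        P = self.params
        T = len(seq) - 1
        hs = np.zeros((T + 1, self.hidden_dim))
        probs = np.zeros((T, self.vocab.size))
        begin = self.vocab.index(self.vocab.begin_token)
        for t in range(T):
            x = P["E"][seq[t]]
            hs[t + 1] = np.tanh(x @ P["Wxh"] + hs[t] @ P["Whh"] + P["bh"])
            logits = hs[t + 1] @ P["Why"] + P["by"]
            logits[begin] = -np.inf
            logits -= logits.max()
            e = np.exp(logits)
            probs[t] = e / e.sum()
        return hs, probs

    def next_token_distribution(self, prefix: list[str]) -> np.ndarray:
        if not prefix:
            prefix = [self.vocab.begin_token]
        seq = self.vocab.encode(list(prefix) + [prefix[-1]])  # dummy target slot
        _, probs = self._forward(seq)
        return probs[-1]

    # -- training ----------------------------------------------------------

    def fit(self, corpus: list[str], epochs: int = 10, lr: float = 5e-3,
            seed: int = 0, clip: float = 5.0) -> list[float]:
        """Train on ``corpus``; returns per-epoch mean per-token NLL."""
        if not corpus:
            raise InputError("empty corpus")
        encoded = [
            self.vocab.encode([self.vocab.begin_token,
                               *tokenize(s, self.vocab), self.vocab.end_token])
            for s in corpus
        ]
        rng = np.random.default_rng(seed)
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(len(encoded))
            total, count = 0.0, 0
            for i in order:
                seq = encoded[i]
                loss, grads = self._loss_and_grads(seq, clip)
                total += loss
                count += len(seq) - 1
                self._adam_step(grads, lr)
            history.append(total / count)
        self.metadata["corpus_size"] = len(corpus)
        self.metadata["epochs"] = int(self.metadata.get("epochs", 0)) + epochs
        return history

    def _loss_and_grads(self, seq: np.ndarray, clip: float):
        P = self.params
        hs, probs = self._forward(seq)
        T = len(seq) - 1
        grads = {k: np.zeros_like(p) for k, p in P.items()}
        dh_next = np.zeros(self.hidden_dim)
        loss = 0.0
        for t in reversed(range(T)):
            target = seq[t + 1]
            loss -= np.log(max(probs[t, target], 1e-300))
            dlogits = probs[t].copy()
            dlogits[target] -= 1.0
            grads["Why"] += np.outer(hs[t + 1], dlogits)
            grads["by"] += dlogits
            dh = P["Why"] @ dlogits + dh_next
            dpre = (1.0 - hs[t + 1] ** 2) * dh
            grads["bh"] += dpre
            grads["Whh"] += np.outer(hs[t], dpre)
            x = P["E"][seq[t]]
            grads["Wxh"] += np.outer(x, dpre)
            grads["E"][seq[t]] += P["Wxh"] @ dpre
            dh_next = P["Whh"] @ dpre
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        if norm > clip:
            for g in grads.values():
                g *= clip / norm
        return loss, grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _state_arrays(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    @classmethod
    def _from_state(cls, vocab, metadata, arrays):
        m = cls(vocab, embed_dim=metadata["embed_dim"],
                hidden_dim=metadata["hidden_dim"], seed=metadata["seed"] or 0)
        m.params = {k: arrays[k] for k in m.params}
        m.metadata = metadata
        return m


def train_prior(corpus: list[str], *, model: str = "rnn", epochs: int = 10,
                seed: int = 0, embed_dim: int = 16, hidden_dim: int = 32,
                order: int = 3) -> PriorModel:
    """Train a prior on a SMILES corpus.

    ``model`` selects the implementation: ``"rnn"`` (default), ``"ngram"``,
    or ``"uniform"`` (ignores the corpus content beyond the vocabulary).
    The returned model's average per-token NLL on the corpus is lower after
    training than before (same seed).
    """
    if not corpus:
        raise InputError("empty corpus")
    vocab = TokenVocabulary.from_corpus(corpus)
    if model == "rnn":
        prior = RecurrentPrior(vocab, embed_dim=embed_dim,
                               hidden_dim=hidden_dim, seed=seed)
        prior.fit(corpus, epochs=epochs, seed=seed)
    elif model == "ngram":
        prior = NGramPrior(vocab, order=order).fit(corpus)
    elif model == "uniform":
        prior = UniformPrior(vocab)
    else:
        raise InputError(f"unknown prior model {model!r}")
    prior.metadata["seed"] = seed
    return prior
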