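"""Skip-gram word embeddings trained with negative sampling (NEG).

The model keeps two dense matrices over the vocabulary: input vectors V(w)
(the embeddings that downstream featurization uses) and output vectors
theta_u (the per-word classifier weights of the NEG objective).  For a
center word w~ and a candidate word u with label L (1 for the observed
context word, 0 for each of the k sampled negatives), the per-pair
log-likelihood is

    log p(u | w~) = L * log sigma(V(w~) . theta_u)
                  + (1 - L) * log(1 - sigma(V(w~) . theta_u))

and the corpus objective is the sum of these terms over every (center,
context) pair and its negatives.  Maximization is plain SGD with a linearly
decaying learning rate; training is single-threaded and bit-reproducible
given the seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import Corpus, Vocabulary, build_vocab

__all__ = [
    "SkipGramParams",
    "SkipGramModel",
    "TrainingPair",
    "sigmoid",
    "draw_negatives",
    "pair_objective",
    "pair_gradients",
    "corpus_objective",
    "freeze_negative_draws",
    "train",
]

SIGMOID_CLAMP = 35.0
LOG_FLOOR = math.log(1e-15)

NEG_DISTRIBUTIONS = ("unigram_pow_0.75", "uniform")


@dataclass(frozen=True)
class SkipGramParams:
    """Training hyperparameters.

    Defaults follow the published setting: 100-dimensional embeddings, a
    symmetric context window of 12 words, and 15 negative samples per
    (center, context) pair.  The learning-rate schedule (0.025 -> 1e-4
    linearly over all scheduled updates, 5 epochs) is the standard Word2vec
    default.
    """

    dim: int = 100
    window: int = 12
    negatives: int = 15
    epochs: int = 5
    lr_start: float = 0.025
    lr_end: float = 1e-4
    neg_distribution: str = "unigram_pow_0.75"
    min_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negatives < 1 or self.epochs < 1:
            raise ValueError("dim, window, negatives and epochs must be >= 1")
        if not (self.lr_start > self.lr_end > 0):
            raise ValueError("require lr_start > lr_end > 0")
        if self.neg_distribution not in NEG_DISTRIBUTIONS:
            raise ValueError(
                f"neg_distribution must be one of {NEG_DISTRIBUTIONS}"
            )


@dataclass(frozen=True)
class TrainingPair:
    center_id: int  # index of w~, the word whose input vector is updated
    target_id: int  # index of u, the word whose output vector is scored
    label: int      # 1 for the observed context word, 0 for a negative

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SkipGramModel:
    vocab: Vocabulary
    input_vectors: np.ndarray   # |V| x dim, V(w)
    output_vectors: np.ndarray  # |V| x dim, theta_u
    params: SkipGramParams

    def __post_init__(self) -> None:
        if self.input_vectors.shape != self.output_vectors.shape:
            raise ValueError("input and output matrices must share a shape")
        if self.input_vectors.shape != (len(self.vocab), self.params.dim):
            raise ValueError("matrix shape does not match (|V|, dim)")
        if not (
            np.isfinite(self.input_vectors).all()
            and np.isfinite(self.output_vectors).all()
        ):
            raise ValueError("embedding matrices must be finite")

    def vector(self, token: str) -> np.ndarray:
        """Input vector V(token); KeyError if the token is out of vocabulary."""
        return self.input_vectors[self.vocab.index(token)]


def sigmoid(x):
    """Numerically stable logistic function; argument clamped to +-35."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -SIGMOID_CLAMP, SIGMOID_CLAMP)))


class _NegativeSampler:
    """Draws negative word indices from the configured noise distribution."""

    def __init__(self, vocab: Vocabulary, distribution: str, rng: np.random.Generator):
        if len(vocab) < 2:
            raise ValueError("need a vocabulary of at least 2 tokens to draw negatives")
        counts = np.array(list(vocab.counts.values()), dtype=float)
        if distribution == "unigram_pow_0.75":
            weights = counts ** 0.75
        elif distribution == "uniform":
            weights = np.ones_like(counts)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        self.probabilities = weights / weights.sum()
        self._cum = np.cumsum(self.probabilities)
        self._cum[-1] = 1.0
        self.rng = rng

    def draw(self, k: int, exclude: int) -> np.ndarray:
        ids = np.searchsorted(self._cum, self.rng.random(k), side="right")
        while True:
            bad = ids == exclude
            n_bad = int(bad.sum())
            if n_bad == 0:
                return ids
            ids[bad] = np.searchsorted(
                self._cum, self.rng.random(n_bad), side="right"
            )


def draw_negatives(
    vocab: Vocabulary,
    k: int,
    exclude: int,
    rng: np.random.Generator,
    distribution: str = "unigram_pow_0.75",
) -> np.ndarray:
    """Draw exactly k negative indices, never equal to ``exclude``.

    Indices are i.i.d. from the noise distribution (default unigram count
    raised to 0.75, renormalized) conditioned on avoiding the excluded word;
    reproducible given the generator state.
    """
    sampler = _NegativeSampler(vocab, distribution, rng)
    return sampler.draw(k, exclude)


def pair_objective(model: SkipGramModel, pair: TrainingPair) -> float:
    """log p(u | w~) for one labeled pair; always <= 0.

    Log terms are floored at log(1e-15) so the objective stays finite even
    for saturated sigmoids.
    """
    dot = float(
        model.input_vectors[pair.center_id] @ model.output_vectors[pair.target_id]
    )
    p = sigmoid(dot)
    val = math.log(p) if pair.label == 1 else math.log(1.0 - p)
    return max(val, LOG_FLOOR)


def pair_gradients(
    model: SkipGramModel, pair: TrainingPair
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of log p(u | w~).

    Returns (d/dV(w~), d/dtheta_u); both equal (L - sigma) times the other
    side's vector.
    """
    v_in = model.input_vectors[pair.center_id]
    theta = model.output_vectors[pair.target_id]
    g = pair.label - sigmoid(float(v_in @ theta))
    return g * theta, g * v_in


def freeze_negative_draws(
    corpus: Corpus,
    vocab: Vocabulary,
    window: int,
    k: int,
    seed: int,
    distribution: str = "unigram_pow_0.75",
) -> list[tuple[int, int, np.ndarray]]:
    """Pre-draw negatives for every (center, context) pair of a corpus.

    The result is a deterministic evaluation set: a list of
    (center_id, context_id, negative_ids) triples on which
    :func:`corpus_objective` is a fixed function of the model matrices.
    """
    rng = np.random.default_rng(seed)
    sampler = _NegativeSampler(vocab, distribution, rng)
    frozen = []
    for sentence in corpus:
        ids = [vocab.index(t) for t in sentence if t in vocab]
        for i, center in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                context = ids[j]
                frozen.append((center, context, sampler.draw(k, exclude=context)))
    return frozen


def corpus_objective(
    model: SkipGramModel, frozen_draws: list[tuple[int, int, np.ndarray]]
) -> float:
    """Corpus log-likelihood over pre-drawn (frozen) negative samples.

    Sum over all (center, context) pairs of the positive term plus the k
    negative terms; deterministic given the frozen draws.
    """
    W_in, W_out = model.input_vectors, model.output_vectors
    total = 0.0
    for center, context, negatives in frozen_draws:
        v_in = W_in[center]
        pos = sigmoid(float(v_in @ W_out[context]))
        total += max(math.log(pos), LOG_FLOOR)
        neg = 1.0 - sigmoid(W_out[negatives] @ v_in)
        total += float(np.maximum(np.log(np.maximum(neg, 1e-300)), LOG_FLOOR).sum())
    return total


def _corpus_hash(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for sentence in corpus:
        h.update(" ".join(sentence.tokens).encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def train(
    corpus: Corpus,
    params: SkipGramParams | None = None,
    vocab: Vocabulary | None = None,
) -> SkipGramModel:
    """Train a Skip-gram NEG model by SGD.

    Sentences are shuffled each epoch with the run seed; within a sentence,
    (center, context) pairs are visited left to right, and each pair incurs
    one positive update and ``negatives`` negative updates.  The learning
    rate decays linearly from ``lr_start`` to ``lr_end`` over all scheduled
    pair updates.  Identical (corpus, params, seed) give bit-identical
    matrices.
    """
    params = params or SkipGramParams()
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    vocab = vocab or build_vocab(corpus, min_count=params.min_count)

    rng = np.random.default_rng(params.seed)
    n_vocab, dim, k = len(vocab), params.dim, params.negatives
    # standard word2vec initialization: small uniform inputs, zero outputs
    W_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    W_out = np.zeros((n_vocab, dim))
    sampler = _NegativeSampler(vocab, params.neg_distribution, rng)

    sentence_ids = [
        np.array([vocab.index(t) for t in s if t in vocab], dtype=np.intp)
        for s in corpus
    ]
    c = params.window

    def n_pairs(length: int) -> int:
        return sum(
            min(length, i + c + 1) - max(0, i - c) - 1 for i in range(length)
        )

    total_updates = params.epochs * sum(n_pairs(len(ids)) for ids in sentence_ids)
    if total_updates == 0:
        raise ValueError("corpus yields no (center, context) pairs")

    labels = np.zeros(k + 1)
    labels[0] = 1.0
    targets = np.empty(k + 1, dtype=np.intp)
    lr_span = params.lr_start - params.lr_end
    step = 0

    for _ in range(params.epochs):
        for s_idx in rng.permutation(len(sentence_ids)):
            ids = sentence_ids[s_idx]
            n = len(ids)
            for i in range(n):
                center = ids[i]
                v_in = W_in[center]
                lo, hi = max(0, i - c), min(n, i + c + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    context = ids[j]
                    lr = params.lr_end + lr_span * (1.0 - step / total_updates)
                    step += 1
                    targets[0] = context
                    targets[1:] = sampler.draw(k, exclude=context)
                    rows = W_out[targets]
                    g = lr * (labels - sigmoid(rows @ v_in))
                    grad_in = g @ rows
                    np.add.at(W_out, targets, np.outer(g, v_in))
                    v_in += grad_in  # in-place view update of W_in[center]

    model = SkipGramModel(
        vocab=vocab,
        input_vectors=W_in,
        output_vectors=W_out,
        params=replace(params),
    )
    model.corpus_hash = _corpus_hash(corpus)
    return model
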