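import math

import numpy as np
import pytest
from scipy.stats import chisquare

from spvec.corpus import Corpus, Sentence, build_vocab, iter_context_pairs
from spvec.skipgram import (
    SkipGramModel,
    SkipGramParams,
    TrainingPair,
    corpus_objective,
    draw_negatives,
    freeze_negative_draws,
    pair_gradients,
    pair_objective,
    sigmoid,
    train,
)


def brute_force_objective(model, frozen_draws):
    """Independent oracle: direct per-term evaluation of the NEG likelihood."""
    total = 0.0
    for center, context, negatives in frozen_draws:
        dot = float(model.input_vectors[center] @ model.output_vectors[context])
        total += max(math.log(1.0 / (1.0 + math.exp(-dot))), math.log(1e-15))
        for u in negatives:
            dot = float(model.input_vectors[center] @ model.output_vectors[u])
            total += max(
                math.log(1.0 - 1.0 / (1.0 + math.exp(-dot))), math.log(1e-15)
            )
    return total


class TestSigmoid:
    def test_zero(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [-5.0, -0.3, 0.7, 4.2])
    def test_symmetry(self, x):
        assert sigmoid(x) == pytest.approx(1.0 - sigmoid(-x), abs=1e-15)

    def test_moderate_argument_exact(self):
        # reference value evaluated with mpmath at 50 digits
        assert sigmoid(35.0) == pytest.approx(0.9999999999999993778, abs=1e-12)

    def test_extreme_arguments_finite(self):
        assert 0.0 < sigmoid(-1e4) < sigmoid(1e4) <= 1.0


class TestDrawNegatives:
    def test_count_and_exclusion(self, random_model):
        rng = np.random.default_rng(0)
        for exclude in range(len(random_model.vocab)):
            ids = draw_negatives(random_model.vocab, 15, exclude, rng)
            assert len(ids) == 15
            assert exclude not in ids

    def test_reproducible_given_state(self, random_model):
        a = draw_negatives(random_model.vocab, 10, 0, np.random.default_rng(5))
        b = draw_negatives(random_model.vocab, 10, 0, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_too_small_vocab_rejected(self):
        vocab = build_vocab(Corpus([Sentence(["C", "C"])]))
        with pytest.raises(ValueError):
            draw_negatives(vocab, 5, 0, np.random.default_rng(0))

    def test_unigram_075_empirical_distribution(self, planted_corpus):
        """Draw frequencies match the count^0.75 noise distribution."""
        vocab = build_vocab(planted_corpus)
        counts = np.array(list(vocab.counts.values()), dtype=float)
        weights = counts**0.75
        # exclude the last index and renormalize the theoretical law
        exclude = len(vocab) - 1
        weights[exclude] = 0.0
        probs = weights / weights.sum()
        rng = np.random.default_rng(123)
        draws = draw_negatives(vocab, 100_000, exclude, rng)
        observed = np.bincount(draws, minlength=len(vocab))
        keep = probs > 0
        _, p = chisquare(observed[keep], probs[keep] * draws.size)
        assert p > 0.01

    def test_uniform_distribution_option(self, planted_corpus):
        vocab = build_vocab(planted_corpus)
        rng = np.random.default_rng(9)
        draws = draw_negatives(vocab, 50_000, 0, rng, distribution="uniform")
        observed = np.bincount(draws, minlength=len(vocab))[1:]
        _, p = chisquare(observed)
        assert p > 0.01


class TestPairObjective:
    def test_zero_output_vector_gives_log_half(self, random_model):
        model = SkipGramModel(
            vocab=random_model.vocab,
            input_vectors=random_model.input_vectors.copy(),
            output_vectors=np.zeros_like(random_model.output_vectors),
            params=random_model.params,
        )
        for label in (0, 1):
            val = pair_objective(model, TrainingPair(0, 1, label))
            assert val == pytest.approx(math.log(0.5), abs=1e-14)

    def test_always_nonpositive(self, random_model):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pair = TrainingPair(
                int(rng.integers(4)), int(rng.integers(4)), int(rng.integers(2))
            )
            assert pair_objective(random_model, pair) <= 0.0

    def test_matches_independent_recomputation(self, random_model):
        rng = np.random.default_rng(2)
        for _ in range(20):
            c, t = int(rng.integers(4)), int(rng.integers(4))
            label = int(rng.integers(2))
            dot = float(
                random_model.input_vectors[c] @ random_model.output_vectors[t]
            )
            p = 1.0 / (1.0 + math.exp(-dot))
            expected = math.log(p if label else 1.0 - p)
            got = pair_objective(random_model, TrainingPair(c, t, label))
            assert got == pytest.approx(expected, rel=1e-12)


class TestPairGradients:
    def test_plug_in_half_sigma(self, random_model):
        """With a zero output vector, sigma = 1/2, so grad wrt theta = V/2."""
        model = SkipGramModel(
            vocab=random_model.vocab,
            input_vectors=random_model.input_vectors.copy(),
            output_vectors=np.zeros_like(random_model.output_vectors),
            params=random_model.params,
        )
        _, g_out = pair_gradients(model, TrainingPair(2, 1, 1))
        assert np.allclose(g_out, 0.5 * model.input_vectors[2])

    def test_zero_input_vector_zeroes_output_gradient(self, random_model):
        W_in = random_model.input_vectors.copy()
        W_in[0] = 0.0
        model = SkipGramModel(
            vocab=random_model.vocab,
            input_vectors=W_in,
            output_vectors=random_model.output_vectors.copy(),
            params=random_model.params,
        )
        _, g_out = pair_gradients(model, TrainingPair(0, 1, 0))
        assert np.allclose(g_out, 0.0)

    def test_finite_difference_agreement(self, random_model):
        """Analytic gradients match central finite differences (rel err < 1e-5)."""
        h = 1e-6
        rng = np.random.default_rng(7)
        model = SkipGramModel(
            vocab=random_model.vocab,
            input_vectors=random_model.input_vectors.copy(),
            output_vectors=random_model.output_vectors.copy(),
            params=random_model.params,
        )
        for _ in range(12):
            pair = TrainingPair(
                int(rng.integers(4)), int(rng.integers(4)), int(rng.integers(2))
            )
            g_in, g_out = pair_gradients(model, pair)
            for matrix, row, grad in (
                (model.input_vectors, pair.center_id, g_in),
                (model.output_vectors, pair.target_id, g_out),
            ):
                numeric = np.empty_like(grad)
                for d in range(matrix.shape[1]):
                    orig = matrix[row, d]
                    matrix[row, d] = orig + h
                    up = pair_objective(model, pair)
                    matrix[row, d] = orig - h
                    down = pair_objective(model, pair)
                    matrix[row, d] = orig
                    numeric[d] = (up - down) / (2 * h)
                denom = max(np.linalg.norm(numeric), 1e-12)
                assert np.linalg.norm(grad - numeric) / denom < 1e-5


class TestCorpusObjective:
    def test_zero_outputs_give_nterms_log_half(self, tiny_corpus, random_model):
        vocab = random_model.vocab
        k = 3
        frozen = freeze_negative_draws(tiny_corpus, vocab, window=2, k=k, seed=0)
        n_pairs = sum(
            len(iter_context_pairs(s, 2)) for s in tiny_corpus
        )
        assert len(frozen) == n_pairs
        model = SkipGramModel(
            vocab=vocab,
            input_vectors=random_model.input_vectors.copy(),
            output_vectors=np.zeros_like(random_model.output_vectors),
            params=random_model.params,
        )
        expected = n_pairs * (1 + k) * math.log(0.5)
        assert corpus_objective(model, frozen) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_enumeration(self, tiny_corpus, random_model):
        frozen = freeze_negative_draws(
            tiny_corpus, random_model.vocab, window=2, k=3, seed=4
        )
        got = corpus_objective(random_model, frozen)
        assert got == pytest.approx(
            brute_force_objective(random_model, frozen), rel=1e-10
        )


class TestTrain:
    def test_seeded_determinism(self, tiny_corpus):
        params = SkipGramParams(dim=8, window=2, negatives=3, epochs=2, seed=99)
        m1 = train(tiny_corpus, params)
        m2 = train(tiny_corpus, params)
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.array_equal(m1.output_vectors, m2.output_vectors)

    def test_different_seeds_differ(self, tiny_corpus):
        p1 = SkipGramParams(dim=8, window=2, negatives=3, epochs=1, seed=1)
        p2 = SkipGramParams(dim=8, window=2, negatives=3, epochs=1, seed=2)
        assert not np.array_equal(
            train(tiny_corpus, p1).input_vectors,
            train(tiny_corpus, p2).input_vectors,
        )

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train(Corpus([]), SkipGramParams())

    def test_objective_ascends_on_frozen_evaluation_set(self, planted_corpus):
        """The NEG log-likelihood increases over training on a fixed set."""
        params = SkipGramParams(dim=16, window=3, negatives=5, epochs=5, seed=0)
        vocab = build_vocab(planted_corpus)
        frozen = freeze_negative_draws(
            planted_corpus, vocab, window=3, k=5, seed=1
        )
        rng = np.random.default_rng(params.seed)
        initial = SkipGramModel(
            vocab=vocab,
            input_vectors=(rng.random((len(vocab), 16)) - 0.5) / 16,
            output_vectors=np.zeros((len(vocab), 16)),
            params=params,
        )
        trained = train(planted_corpus, params, vocab=vocab)
        assert corpus_objective(trained, frozen) > corpus_objective(initial, frozen)

    def test_planted_groups_separate_in_cosine(self, planted_corpus):
        """Tokens that co-occur end up closer than tokens that never do."""
        params = SkipGramParams(dim=16, window=3, negatives=5, epochs=5, seed=0)
        model = train(planted_corpus, params)
        groups = (["A", "B", "C", "D"], ["W", "X", "Y", "Z"])
        vecs = {t: model.vector(t) for g in groups for t in g}

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        within, between = [], []
        tokens = [t for g in groups for t in g]
        for i, a in enumerate(tokens):
            for b in tokens[i + 1 :]:
                same = (a in groups[0]) == (b in groups[0])
                (within if same else between).append(cos(vecs[a], vecs[b]))
        assert np.mean(within) > np.mean(between)

    def test_matrices_finite_after_training(self, tiny_corpus):
        model = train(
            tiny_corpus, SkipGramParams(dim=8, window=2, negatives=3, seed=0)
        )
        assert np.isfinite(model.input_vectors).all()
        assert np.isfinite(model.output_vectors).all()


class TestCrossCheckReferenceTrainer:
    """Neighbor-structure agreement with an independently coded SGD trainer.

    The reference below shares no code with the package trainer: it
    enumerates pairs with its own loops, uses its own sampler and plain
    per-coordinate updates.  On a planted two-group corpus the two
    implementations must agree on most nearest neighbors.
    """

    @staticmethod
    def _reference_train(corpus, vocab, dim, window, k, epochs, seed):
        rng = np.random.default_rng(seed)
        V = len(vocab)
        W_in = (rng.random((V, dim)) - 0.5) / dim
        W_out = np.zeros((V, dim))
        counts = np.array(list(vocab.counts.values()), dtype=float) ** 0.75
        probs = counts / counts.sum()
        lr = 0.025
        for _ in range(epochs):
            for sentence in corpus:
                ids = [vocab.index(t) for t in sentence]
                for i, center in enumerate(ids):
                    for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                        if j == i:
                            continue
                        candidates = [(ids[j], 1)]
                        while len(candidates) < k + 1:
                            neg = rng.choice(V, p=probs)
                            if neg != ids[j]:
                                candidates.append((int(neg), 0))
                        for u, label in candidates:
                            z = 1.0 / (1.0 + np.exp(-W_in[center] @ W_out[u]))
                            g = lr * (label - z)
                            delta_in = g * W_out[u]
                            W_out[u] += g * W_in[center]
                            W_in[center] += delta_in
        return W_in

    def test_nearest_neighbor_agreement(self, planted_corpus):
        vocab = build_vocab(planted_corpus)
        params = SkipGramParams(dim=16, window=3, negatives=5, epochs=3, seed=0)
        model = train(planted_corpus, params, vocab=vocab)
        ref = self._reference_train(
            planted_corpus, vocab, dim=16, window=3, k=5, epochs=3, seed=1
        )

        def top3(matrix):
            norm = matrix / np.linalg.norm(matrix, axis=1, keepdims=True)
            sim = norm @ norm.T
            np.fill_diagonal(sim, -np.inf)
            return [set(np.argsort(-row)[:3]) for row in sim]

        ours = top3(model.input_vectors)
        theirs = top3(ref)
        overlap = np.mean(
            [len(a & b) / 3 for a, b in zip(ours, theirs)]
        )
        assert overlap >= 0.6
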