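import numpy as np
import pytest

from spvec.corpus import Corpus, Sentence, build_vocab
from spvec.datasets import SynthConfig, generate_synthetic
from spvec.skipgram import SkipGramModel, SkipGramParams, train


@pytest.fixture(scope="session")
def tiny_corpus() -> Corpus:
    """Four short sentences over a 4-token vocabulary."""
    return Corpus(
        [
            Sentence(["A", "B", "A", "C"]),
            Sentence(["B", "A", "B"]),
            Sentence(["C", "D", "C"]),
            Sentence(["D", "C", "A"]),
        ],
        kind="smiles",
    )


@pytest.fixture(scope="session")
def random_model(tiny_corpus) -> SkipGramModel:
    """An untrained model with random matrices, for objective/gradient checks."""
    vocab = build_vocab(tiny_corpus)
    rng = np.random.default_rng(42)
    params = SkipGramParams(dim=8, window=2, negatives=3, seed=42)
    return SkipGramModel(
        vocab=vocab,
        input_vectors=rng.normal(scale=0.5, size=(len(vocab), 8)),
        output_vectors=rng.normal(scale=0.5, size=(len(vocab), 8)),
        params=params,
    )


@pytest.fixture(scope="session")
def planted_corpus() -> Corpus:
    """Two disjoint token groups that never co-occur across groups."""
    rng = np.random.default_rng(3)
    group_a = ["A", "B", "C", "D"]
    group_b = ["W", "X", "Y", "Z"]
    sentences = []
    for i in range(60):
        group = group_a if i % 2 == 0 else group_b
        tokens = [group[j] for j in rng.integers(0, 4, size=12)]
        sentences.append(Sentence(tokens))
    return Corpus(sentences, kind="smiles")


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-structure DTI dataset for dataset-level tests."""
    return generate_synthetic(
        SynthConfig(
            drugs_per_class=10,
            targets_per_class=5,
            protein_length=(60, 90),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def study_pipeline():
    """The full desk-scale pipeline at the study conditions.

    2 latent classes, 100 drugs, 50 proteins, label noise 0.05, fixed seed:
    synthetic dataset -> tokenize -> skip-gram embeddings -> SPVec pair
    features -> GBDT repeated CV.  Session-scoped because embedding
    training plus 10x5-fold CV is the most expensive computation the suite
    performs; every consumer reuses one run.
    """
    from spvec.evalbench import CVProtocol, run_cv
    from spvec.pipeline import spvec_features

    dataset = generate_synthetic(SynthConfig(seed=7))
    features, labels = spvec_features(dataset, SkipGramParams(seed=1))
    report = run_cv(features, labels, "gbdt", CVProtocol(folds=5, repeats=10, seed=0))
    return {
        "dataset": dataset,
        "features": features,
        "labels": labels,
        "report": report,
    }
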