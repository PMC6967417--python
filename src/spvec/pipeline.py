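"""End-to-end glue: from a DTI dataset to pair features and labels.

Trains the two embedding models (SMILES corpus for drugs, 3-mer corpus for
proteins), embeds the records, and concatenates rows for the labeled pairs.
This is the path the benchmark exercises: tokenize -> skip-gram ->
SMILES2Vec/ProtVec -> SPVec -> classifier.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .corpus import Corpus, tokenize_protein, tokenize_smiles
from .featurize import FeatureBlock, PairFeatures, aac, combine, embed_records, maccs
from .records import DTIDataset
from .skipgram import SkipGramModel, SkipGramParams, train

__all__ = [
    "build_corpora",
    "train_embeddings",
    "spvec_features",
    "baseline_block",
    "labels_for",
]


def build_corpora(
    dataset: DTIDataset, frame_mode: str = "three_frames"
) -> tuple[Corpus, Corpus]:
    """SMILES-sentence and protein-3-mer corpora for one dataset."""
    smiles_corpus = Corpus(
        [tokenize_smiles(d.smiles, source_id=d.id) for d in dataset.drugs],
        kind="smiles",
    )
    protein_sentences = []
    for t in dataset.targets:
        protein_sentences.extend(tokenize_protein(t.sequence, frame_mode, t.id))
    return smiles_corpus, Corpus(protein_sentences, kind="protein")


def train_embeddings(
    dataset: DTIDataset,
    params: SkipGramParams | None = None,
    frame_mode: str = "three_frames",
) -> tuple[SkipGramModel, SkipGramModel]:
    """Train the drug and protein skip-gram models on one dataset.

    The protein model reuses the same hyperparameters with a derived seed so
    the two models are independently reproducible.
    """
    params = params or SkipGramParams()
    smiles_corpus, protein_corpus = build_corpora(dataset, frame_mode)
    drug_model = train(smiles_corpus, params)
    protein_model = train(protein_corpus, replace(params, seed=params.seed + 1))
    return drug_model, protein_model


def baseline_block(dataset: DTIDataset, scheme: str) -> FeatureBlock:
    """Classical feature blocks: MACCS for drugs or AAC for proteins."""
    if scheme == "maccs":
        rows = [maccs(d.smiles) for d in dataset.drugs]
        return FeatureBlock([d.id for d in dataset.drugs], np.vstack(rows), "maccs")
    if scheme == "aac":
        rows = [aac(t.sequence) for t in dataset.targets]
        return FeatureBlock([t.id for t in dataset.targets], np.vstack(rows), "aac")
    raise ValueError(f"unknown baseline scheme {scheme!r}")


def spvec_features(
    dataset: DTIDataset,
    params: SkipGramParams | None = None,
    aggregation: str = "sum",
    frame_mode: str = "three_frames",
) -> tuple[PairFeatures, np.ndarray]:
    """SPVec pair features and binary labels for a dataset's labeled pairs."""
    drug_model, protein_model = train_embeddings(dataset, params, frame_mode)
    drug_block = embed_records(drug_model, dataset.drugs, aggregation)
    protein_block = embed_records(
        protein_model, dataset.targets, aggregation, frame_mode
    )
    labeled = [r for r in dataset.interactions if r.label in ("positive", "negative")]
    pairs = [r.pair for r in labeled]
    y = np.array([1 if r.label == "positive" else 0 for r in labeled])
    return combine(drug_block, protein_block, pairs), y


def labels_for(dataset: DTIDataset) -> np.ndarray:
    labeled = [r for r in dataset.interactions if r.label in ("positive", "negative")]
    return np.array([1 if r.label == "positive" else 0 for r in labeled])
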