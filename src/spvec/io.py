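"""Readers and writers for the package's flat-file formats.

Molecules come from .smi files (one SMILES plus optional whitespace-
separated identifier per line), proteins from FASTA, interactions from a
headered TSV (drug_id, target_id, label, ic50_nM, date_added; empty field
means missing).  Embedding matrices use the word2vec text format: a header
line "<vocab_size> <dim>" followed by one line per token.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus, Sentence, Vocabulary
from .featurize import FeatureBlock, PairFeatures
from .records import DTIDataset, InteractionRecord, MoleculeRecord, ProteinRecord
from .skipgram import SkipGramModel, SkipGramParams

INTERACTION_COLUMNS = ["drug_id", "target_id", "label", "ic50_nM", "date_added"]


# ---------------------------------------------------------------- records

def read_smi(path) -> list[MoleculeRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        rid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        records.append(MoleculeRecord(rid, smiles))
    return records


def write_smi(path, molecules: list[MoleculeRecord]) -> None:
    lines = [f"{m.smiles}\t{m.id}" for m in molecules]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    return [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, proteins: list[ProteinRecord]) -> None:
    lines = []
    for p in proteins:
        lines.append(f">{p.id}")
        for i in range(0, len(p.sequence), 60):
            lines.append(p.sequence[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def read_interactions(path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"drug_id", "target_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        ic50 = getattr(row, "ic50_nM", "")
        date = getattr(row, "date_added", "")
        records.append(
            InteractionRecord(
                drug_id=row.drug_id,
                target_id=row.target_id,
                label=row.label,
                ic50_nM=float(ic50) if ic50 else None,
                date_added=datetime.date.fromisoformat(date) if date else None,
            )
        )
    return records


def write_interactions(path, interactions: list[InteractionRecord]) -> None:
    rows = [
        {
            "drug_id": r.drug_id,
            "target_id": r.target_id,
            "label": r.label,
            "ic50_nM": "" if r.ic50_nM is None else repr(r.ic50_nM),
            "date_added": "" if r.date_added is None else r.date_added.isoformat(),
        }
        for r in interactions
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dataset(directory, dataset: DTIDataset) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_smi(directory / "drugs.smi", dataset.drugs)
    write_fasta(directory / "targets.fasta", dataset.targets)
    write_interactions(directory / "interactions.tsv", dataset.interactions)


def read_dataset(directory, name: str | None = None) -> DTIDataset:
    directory = Path(directory)
    return DTIDataset(
        drugs=read_smi(directory / "drugs.smi"),
        targets=read_fasta(directory / "targets.fasta"),
        interactions=read_interactions(directory / "interactions.tsv"),
        name=name or directory.name,
    )


# ----------------------------------------------------------------- corpus

def write_corpus(path, corpus: Corpus) -> None:
    lines = [" ".join(s.tokens) for s in corpus]
    Path(path).write_text("\n".join(lines) + "\n")


def read_corpus(path, kind: str = "smiles") -> Corpus:
    sentences = [
        Sentence(line.split())
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    return Corpus(sentences, kind=kind)


# ------------------------------------------------------- embedding models

def _write_word2vec(path, tokens: list[str], matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for token, row in zip(tokens, matrix):
            fh.write(token + " " + " ".join(repr(float(x)) for x in row) + "\n")


def _read_word2vec(path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    n, dim = map(int, lines[0].split())
    tokens, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split(" ")
        tokens.append(parts[0])
        rows.append([float(x) for x in parts[1 : dim + 1]])
    return tokens, np.array(rows)


def save_model(prefix, model: SkipGramModel) -> None:
    """Persist a model: input vectors, output-vector sidecar, JSON metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tokens = model.vocab.tokens
    _write_word2vec(f"{prefix}.vectors.txt", tokens, model.input_vectors)
    _write_word2vec(f"{prefix}.out.txt", tokens, model.output_vectors)
    meta = {
        "params": {
            k: getattr(model.params, k)
            for k in (
                "dim", "window", "negatives", "epochs", "lr_start",
                "lr_end", "neg_distribution", "min_count", "seed",
            )
        },
        "counts": model.vocab.counts,
        "min_count": model.vocab.min_count,
        "corpus_hash": getattr(model, "corpus_hash", None),
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta, indent=1))


def load_model(prefix) -> SkipGramModel:
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    vocab = Vocabulary(meta["counts"], min_count=meta["min_count"])
    tokens, W_in = _read_word2vec(f"{prefix}.vectors.txt")
    _, W_out = _read_word2vec(f"{prefix}.out.txt")
    if tokens != vocab.tokens:
        raise ValueError("vector file token order disagrees with metadata counts")
    model = SkipGramModel(
        vocab=vocab,
        input_vectors=W_in,
        output_vectors=W_out,
        params=SkipGramParams(**meta["params"]),
    )
    model.corpus_hash = meta.get("corpus_hash")
    return model


# ----------------------------------------------------------- feature I/O

def write_features(path, block: FeatureBlock) -> None:
    df = pd.DataFrame(block.matrix, columns=[f"f{i}" for i in range(block.p)])
    df.insert(0, "id", block.ids)
    df.insert(1, "scheme", block.scheme)
    df.to_csv(path, sep="\t", index=False)


def read_features(path) -> FeatureBlock:
    df = pd.read_csv(path, sep="\t")
    scheme = df["scheme"].iloc[0]
    matrix = df.drop(columns=["id", "scheme"]).to_numpy(dtype=float)
    return FeatureBlock(list(df["id"].astype(str)), matrix, scheme)


def write_pair_features(path, pf: PairFeatures) -> None:
    df = pd.DataFrame(pf.matrix, columns=[f"f{i}" for i in range(pf.matrix.shape[1])])
    df.insert(0, "drug_id", [d for d, _ in pf.pairs])
    df.insert(1, "target_id", [t for _, t in pf.pairs])
    df.insert(2, "combo", pf.combo)
    df.to_csv(path, sep="\t", index=False)


def read_pair_features(path) -> PairFeatures:
    df = pd.read_csv(path, sep="\t")
    combo = df["combo"].iloc[0]
    pairs = list(zip(df["drug_id"].astype(str), df["target_id"].astype(str)))
    matrix = df.drop(columns=["drug_id", "target_id", "combo"]).to_numpy(dtype=float)
    return PairFeatures(pairs, matrix, combo)
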