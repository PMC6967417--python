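"""Fixed-length feature vectors for molecules, proteins and pairs.

Embedding-based schemes sum (or average) a trained model's input vectors
over a record's tokens: SMILES2Vec for molecules, ProtVec for proteins.
Classical baselines are the 166-key MACCS structural fingerprint (via
RDKit) and the 20-dimensional amino-acid composition (AAC).  A drug-target
pair is represented by concatenating the drug block row with the target
block row; the SMILES2Vec + ProtVec concatenation is the SPVec pair vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .corpus import Sentence, tokenize_protein, tokenize_smiles
from .records import MoleculeRecord, ProteinRecord
from .skipgram import SkipGramModel

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBlock",
    "PairFeatures",
    "STANDARD_RESIDUES",
    "sentence_vector",
    "embed_records",
    "aac",
    "maccs",
    "combine",
    "property_profile",
    "residue_scales",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

SCHEMES = ("smiles2vec", "protvec", "maccs", "aac")

# Table 2-style names for each (drug scheme, protein scheme) concatenation.
COMBO_NAMES = {
    ("smiles2vec", "protvec"): "SPVec",
    ("smiles2vec", "aac"): "SMILES2Vec-AAC",
    ("maccs", "protvec"): "MACCS-ProtVec",
    ("maccs", "aac"): "MACCS-AAC",
}


@dataclass
class FeatureBlock:
    ids: list[str]
    matrix: np.ndarray
    scheme: str
    flagged_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix rows must align with ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in feature block")
        self._row = {rid: i for i, rid in enumerate(self.ids)}

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def row(self, record_id: str) -> np.ndarray:
        return self.matrix[self._row[record_id]]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._row


@dataclass
class PairFeatures:
    pairs: list[tuple[str, str]]
    matrix: np.ndarray
    combo: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.pairs):
            raise ValueError("matrix rows must align with pairs")


def sentence_vector(
    model: SkipGramModel,
    sentences: Sentence | list[Sentence],
    aggregation: str = "sum",
) -> np.ndarray:
    """Aggregate input vectors V(token) over one or more sentences.

    Out-of-vocabulary tokens are skipped (counted and logged); if every
    token is OOV the zero vector is returned.  Under ``sum`` aggregation the
    map is additive over sentence concatenation.
    """
    if aggregation not in ("sum", "mean"):
        raise ValueError("aggregation must be 'sum' or 'mean'")
    if isinstance(sentences, Sentence):
        sentences = [sentences]
    ids = [
        model.vocab.index(t)
        for s in sentences
        for t in s
        if t in model.vocab
    ]
    n_total = sum(len(s) for s in sentences)
    n_oov = n_total - len(ids)
    if n_oov:
        logger.debug("sentence_vector: %d/%d tokens out of vocabulary", n_oov, n_total)
    if not ids:
        return np.zeros(model.params.dim)
    vec = model.input_vectors[ids].sum(axis=0)
    if aggregation == "mean":
        vec = vec / len(ids)
    return vec


def embed_records(
    model: SkipGramModel,
    records: list[MoleculeRecord] | list[ProteinRecord],
    aggregation: str = "sum",
    frame_mode: str = "three_frames",
    granularity: str = "atom",
) -> FeatureBlock:
    """Embed a batch of molecule or protein records into a feature block.

    Molecules are tokenized as SMILES sentences, proteins as non-overlapping
    3-mer sentences (all frames aggregated together).  Records whose tokens
    are entirely out of vocabulary get a zero row and are flagged.
    """
    if not records:
        raise ValueError("no records to embed")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    is_protein = isinstance(records[0], ProteinRecord)
    rows, flagged = [], []
    for rec in records:
        if is_protein:
            sents = tokenize_protein(rec.sequence, frame_mode, source_id=rec.id)
        else:
            sents = [tokenize_smiles(rec.smiles, source_id=rec.id, granularity=granularity)]
        vec = sentence_vector(model, sents, aggregation)
        if not np.any(vec):
            flagged.append(rec.id)
        rows.append(vec)
    scheme = "protvec" if is_protein else "smiles2vec"
    return FeatureBlock(ids, np.vstack(rows), scheme, flagged_ids=flagged)


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: the 20-vector of standard-residue fractions.

    Nonstandard letters are excluded from both numerator and denominator,
    so the components always sum to 1 when at least one standard residue is
    present.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.array([sequence.count(res) for res in STANDARD_RESIDUES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    return counts / total


def maccs(smiles: str) -> np.ndarray:
    """The 166 public MACCS keys as a binary vector (RDKit-backed)."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    arr = np.zeros(167, dtype=float)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr[1:]


def combine(
    drug_block: FeatureBlock,
    protein_block: FeatureBlock,
    pairs: list[tuple[str, str]],
) -> PairFeatures:
    """Concatenate drug and protein feature rows for each (drug, target) pair."""
    missing = [
        (d, t)
        for d, t in pairs
        if d not in drug_block or t not in protein_block
    ]
    if missing:
        raise KeyError(f"pairs reference unknown ids: {missing[:5]}")
    matrix = np.empty((len(pairs), drug_block.p + protein_block.p))
    for i, (d, t) in enumerate(pairs):
        matrix[i, : drug_block.p] = drug_block.row(d)
        matrix[i, drug_block.p :] = protein_block.row(t)
    combo = COMBO_NAMES.get(
        (drug_block.scheme, protein_block.scheme),
        f"{drug_block.scheme}-{protein_block.scheme}",
    )
    return PairFeatures(list(pairs), matrix, combo)


def residue_scales() -> dict[str, dict[str, float]]:
    """The shipped per-residue property tables (mass, volume, polarity, hydrophobicity)."""
    text = resources.files("spvec.data").joinpath("residue_scales.json").read_text()
    payload = json.loads(text)
    return {name: entry["values"] for name, entry in payload["scales"].items()}


def property_profile(sequence: str) -> dict[str, float]:
    """Per-protein mean of each per-residue property scale.

    Used to color low-dimensional projections of protein embeddings;
    nonstandard residues are ignored.
    """
    standard = [r for r in sequence if r in STANDARD_RESIDUES]
    if not standard:
        raise ValueError("sequence contains no standard residues")
    scales = residue_scales()
    return {
        name: float(np.mean([table[r] for r in standard]))
        for name, table in scales.items()
    }
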