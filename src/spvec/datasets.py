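"""Dataset construction: affinity/identity/inorganic filters, negative
sampling from the unlabeled pool, temporal splitting, and a seeded
synthetic generator with planted, learnable class structure.

The filters mirror common curation of binding databases: keep only
interactions with a measured IC50 of at most 300 nM, drop carbon-free
("inorganic") compounds, and collapse protein targets sharing more than
75% global-alignment sequence identity.  The temporal split partitions a
dated interaction ledger into five datasets by whether each drug, target
and interaction predates a cutoff.
"""

from __future__ import annotations

import datetime
import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import tokenize_smiles
from .records import DTIDataset, InteractionRecord, MoleculeRecord, ProteinRecord

__all__ = [
    "SynthConfig",
    "filter_by_affinity",
    "filter_redundant_targets",
    "filter_inorganic",
    "sample_negatives",
    "temporal_split",
    "generate_synthetic",
]

_BRACKET_ELEMENT = re.compile(r"\[(?:\d+)?([A-Za-z][a-z]?)")


def filter_by_affinity(
    records: list[InteractionRecord], max_ic50_nM: float = 300.0
) -> list[InteractionRecord]:
    """Keep interactions with a present IC50 of at most ``max_ic50_nM``.

    The boundary value is kept (only strictly greater affinities are
    excluded); records with a missing IC50 are always dropped.
    """
    kept = [
        r for r in records if r.ic50_nM is not None and r.ic50_nM <= max_ic50_nM
    ]
    if records and not kept:
        warnings.warn("affinity filter removed every record", stacklevel=2)
    return kept


def _alignment_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matched positions / alignment length."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-10,
        extend_gap_score=-0.5,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def filter_redundant_targets(
    proteins: list[ProteinRecord], identity_threshold: float = 0.75
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy longest-first clustering of near-identical targets.

    Proteins are visited by descending sequence length (ties by id); each is
    kept unless its identity with an already-kept representative exceeds the
    threshold, in which case it is mapped to that representative.  Returns
    the representatives and a member-id -> representative-id map.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    kept: list[ProteinRecord] = []
    cluster: dict[str, str] = {}
    for prot in ordered:
        rep = None
        for ref in kept:
            if _alignment_identity(prot.sequence, ref.sequence) > identity_threshold:
                rep = ref
                break
        if rep is None:
            kept.append(prot)
            cluster[prot.id] = prot.id
        else:
            cluster[prot.id] = rep.id
    order = {p.id: i for i, p in enumerate(proteins)}
    kept.sort(key=lambda p: order[p.id])
    return kept, cluster


def _has_carbon(smiles: str) -> bool:
    for token in tokenize_smiles(smiles).tokens:
        if token in ("C", "c"):
            return True
        if token.startswith("["):
            m = _BRACKET_ELEMENT.match(token)
            if m and m.group(1) in ("C", "c"):
                return True
    return False


def filter_inorganic(molecules: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep molecules whose SMILES contains at least one carbon atom token."""
    return [m for m in molecules if _has_carbon(m.smiles)]


def sample_negatives(
    positives: set[tuple[str, str]],
    drug_ids: list[str],
    target_ids: list[str],
    n: int,
    seed: int,
    exclusion: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Sample n presumed-negative pairs uniformly from the unlabeled pool.

    The pool is every (drug, target) combination minus the positives and any
    extra exclusion set; sampling is without replacement and seeded.
    """
    excluded = set(positives) | (set(exclusion) if exclusion else set())
    pool = [
        pair
        for pair in itertools.product(sorted(drug_ids), sorted(target_ids))
        if pair not in excluded
    ]
    if len(pool) < n:
        raise ValueError(
            f"unlabeled pool has only {len(pool)} pairs; cannot sample {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def temporal_split(
    drugs: list[MoleculeRecord],
    targets: list[ProteinRecord],
    interactions: list[InteractionRecord],
    cutoff_date: datetime.date,
    entity_dates: dict[str, datetime.date] | None = None,
) -> dict[str, DTIDataset]:
    """Partition a dated interaction ledger into the five temporal datasets.

    An entity (drug or target) is "old" iff its first-appearance date is
    before the cutoff; otherwise "new".  Entity dates come from
    ``entity_dates`` when provided, else from the earliest interaction date
    the entity participates in.  Interactions are assigned:

    - dataset_1: old drug x old target, interaction dated before the cutoff
    - dataset_2: old drug x old target, interaction dated on/after the cutoff
    - dataset_3: new drug x old target (any interaction date)
    - dataset_4: old drug x new target (any interaction date)
    - dataset_5: new drug x new target (any interaction date)

    The five interaction sets are disjoint and jointly cover the ledger.
    """
    undated = [r for r in interactions if r.date_added is None]
    if undated:
        raise ValueError(
            f"interactions without dates: {[r.pair for r in undated[:5]]}"
        )
    dates: dict[str, datetime.date] = dict(entity_dates or {})
    if entity_dates is None:
        for rec in interactions:
            for eid in (rec.drug_id, rec.target_id):
                if eid not in dates or rec.date_added < dates[eid]:
                    dates[eid] = rec.date_added
    missing = [
        e.id for e in itertools.chain(drugs, targets) if e.id not in dates
    ]
    if missing:
        raise ValueError(f"entities without a first-appearance date: {missing[:5]}")

    def is_old(eid: str) -> bool:
        return dates[eid] < cutoff_date

    buckets: dict[str, list[InteractionRecord]] = {
        f"dataset_{i}": [] for i in range(1, 6)
    }
    for rec in interactions:
        old_d, old_t = is_old(rec.drug_id), is_old(rec.target_id)
        if old_d and old_t:
            key = "dataset_1" if rec.date_added < cutoff_date else "dataset_2"
        elif not old_d and old_t:
            key = "dataset_3"
        elif old_d and not old_t:
            key = "dataset_4"
        else:
            key = "dataset_5"
        buckets[key].append(rec)

    drug_by_id = {d.id: d for d in drugs}
    target_by_id = {t.id: t for t in targets}
    old_drugs = [d for d in drugs if is_old(d.id)]
    new_drugs = [d for d in drugs if not is_old(d.id)]
    old_targets = [t for t in targets if is_old(t.id)]
    new_targets = [t for t in targets if not is_old(t.id)]
    entity_sets = {
        "dataset_1": (old_drugs, old_targets),
        "dataset_2": (old_drugs, old_targets),
        "dataset_3": (new_drugs, old_targets),
        "dataset_4": (old_drugs, new_targets),
        "dataset_5": (new_drugs, new_targets),
    }
    out = {}
    for name, recs in buckets.items():
        ds_drugs, ds_targets = entity_sets[name]
        # ensure referenced entities are present even under entity_dates overrides
        ds_drug_ids = {d.id for d in ds_drugs}
        ds_target_ids = {t.id for t in ds_targets}
        for rec in recs:
            if rec.drug_id not in ds_drug_ids:
                ds_drugs = ds_drugs + [drug_by_id[rec.drug_id]]
                ds_drug_ids.add(rec.drug_id)
            if rec.target_id not in ds_target_ids:
                ds_targets = ds_targets + [target_by_id[rec.target_id]]
                ds_target_ids.add(rec.target_id)
        out[name] = DTIDataset(ds_drugs, ds_targets, recs, name=name)
    return out


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic DTI generator.

    Drugs are random token strings over a shared SMILES-like alphabet,
    enriched in a class-specific token set; proteins are random sequences
    with class-specific 3-mer motifs planted into non-overlapping word
    slots.  A pair is truly positive iff the drug and target classes match
    (class i with class i), and the observed label flips with probability
    ``label_noise``.  Positives get an IC50 of at most 300 nM; negatives
    get either a missing IC50 or one above 300 nM.  Interaction dates fall
    before the cutoff with probability ``1 - new_fraction``.
    """

    n_drug_classes: int = 2
    n_target_classes: int = 2
    drugs_per_class: int = 50
    targets_per_class: int = 25
    smiles_length: tuple[int, int] = (20, 40)
    protein_length: tuple[int, int] = (90, 150)
    shared_alphabet: tuple[str, ...] = ("C", "c", "O", "1", "2", "=")
    class_tokens: tuple[tuple[str, ...], ...] = (("N", "F"), ("S", "I"))
    enrichment_rate: float = 0.3
    motifs_per_class: int = 3
    motif_rate: float = 0.3
    label_noise: float = 0.05
    cutoff_date: datetime.date = datetime.date(2016, 4, 20)
    new_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drug_classes != len(self.class_tokens):
            raise ValueError("need one class token set per drug class")
        flat = [t for group in self.class_tokens for t in group]
        if len(flat) != len(set(flat)):
            raise ValueError("class token sets must be disjoint")
        if set(flat) & set(self.shared_alphabet):
            raise ValueError("class tokens must not appear in the shared alphabet")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 < self.enrichment_rate <= 1 or not 0 < self.motif_rate <= 1:
            raise ValueError("enrichment_rate and motif_rate must lie in (0, 1]")


_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _random_date(
    rng: np.random.Generator, cutoff: datetime.date, new: bool
) -> datetime.date:
    offset = int(rng.integers(1, 365))
    delta = datetime.timedelta(days=offset)
    return cutoff + delta if new else cutoff - delta


def generate_synthetic(config: SynthConfig | None = None) -> DTIDataset:
    """Generate a fully seeded synthetic DTI dataset with planted structure."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    drugs: list[MoleculeRecord] = []
    drug_class: dict[str, int] = {}
    for cls in range(cfg.n_drug_classes):
        tokens_cls = cfg.class_tokens[cls]
        for i in range(cfg.drugs_per_class):
            length = int(rng.integers(cfg.smiles_length[0], cfg.smiles_length[1] + 1))
            chars = [
                tokens_cls[rng.integers(len(tokens_cls))]
                if rng.random() < cfg.enrichment_rate
                else cfg.shared_alphabet[rng.integers(len(cfg.shared_alphabet))]
                for _ in range(length)
            ]
            did = f"D{cls}{i:04d}"
            drugs.append(MoleculeRecord(did, "".join(chars)))
            drug_class[did] = cls

    # disjoint random 3-mer motifs per target class
    motifs: list[list[str]] = []
    used: set[str] = set()
    for _ in range(cfg.n_target_classes):
        group: list[str] = []
        while len(group) < cfg.motifs_per_class:
            mer = "".join(_RESIDUES[j] for j in rng.integers(0, 20, size=3))
            if mer not in used:
                used.add(mer)
                group.append(mer)
        motifs.append(group)

    targets: list[ProteinRecord] = []
    target_class: dict[str, int] = {}
    for cls in range(cfg.n_target_classes):
        for i in range(cfg.targets_per_class):
            length = int(
                rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1)
            )
            seq = list(_RESIDUES[j] for j in rng.integers(0, 20, size=length))
            for start in range(0, length - 2, 3):
                if rng.random() < cfg.motif_rate:
                    motif = motifs[cls][int(rng.integers(cfg.motifs_per_class))]
                    seq[start : start + 3] = motif
            tid = f"T{cls}{i:04d}"
            targets.append(ProteinRecord(tid, "".join(seq)))
            target_class[tid] = cls

    interactions: list[InteractionRecord] = []
    for drug in drugs:
        for target in targets:
            truly_positive = drug_class[drug.id] == target_class[target.id]
            label_positive = truly_positive ^ (rng.random() < cfg.label_noise)
            if label_positive:
                ic50 = float(rng.uniform(1.0, 300.0))
            else:
                ic50 = (
                    None
                    if rng.random() < 0.5
                    else float(rng.uniform(301.0, 10000.0))
                )
            date = _random_date(
                rng, cfg.cutoff_date, new=rng.random() < cfg.new_fraction
            )
            interactions.append(
                InteractionRecord(
                    drug_id=drug.id,
                    target_id=target.id,
                    label="positive" if label_positive else "negative",
                    ic50_nM=ic50,
                    date_added=date,
                )
            )
    return DTIDataset(drugs, targets, interactions, name=f"synthetic_seed{cfg.seed}")
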