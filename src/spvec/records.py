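"""Core record types shared across the package.

A molecule is a SMILES string with an identifier, a protein is an amino-acid
sequence with an identifier, and an interaction links one of each with a
label and optional BindingDB-style annotations (an IC50 in nM and the date
the interaction entered the source ledger).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

LABELS = ("positive", "negative", "unlabeled")


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if not self.smiles:
            raise ValueError(f"molecule {self.id!r}: empty SMILES")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class InteractionRecord:
    drug_id: str
    target_id: str
    label: str = "unlabeled"
    ic50_nM: float | None = None
    date_added: datetime.date | None = None

    def __post_init__(self) -> None:
        if not self.drug_id or not self.target_id:
            raise ValueError("interaction ids must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.ic50_nM is not None and not self.ic50_nM > 0:
            raise ValueError(
                f"({self.drug_id}, {self.target_id}): ic50_nM must be positive"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.target_id)


@dataclass
class DTIDataset:
    """A self-contained drug-target interaction dataset.

    Every interaction's drug and target ids must resolve against the record
    lists, and no pair may be both positive and negative.
    """

    drugs: list[MoleculeRecord]
    targets: list[ProteinRecord]
    interactions: list[InteractionRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        drug_ids = {d.id for d in self.drugs}
        target_ids = {t.id for t in self.targets}
        pos, neg = set(), set()
        for rec in self.interactions:
            if rec.drug_id not in drug_ids:
                raise ValueError(f"{self.name}: unknown drug id {rec.drug_id!r}")
            if rec.target_id not in target_ids:
                raise ValueError(f"{self.name}: unknown target id {rec.target_id!r}")
            if rec.label == "positive":
                pos.add(rec.pair)
            elif rec.label == "negative":
                neg.add(rec.pair)
        overlap = pos & neg
        if overlap:
            raise ValueError(
                f"{self.name}: pairs labeled both positive and negative: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def positives(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.interactions if r.label == "positive"}

    @property
    def negatives(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.interactions if r.label == "negative"}
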