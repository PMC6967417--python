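"""Tokenization of SMILES strings and protein sequences into word corpora.

SMILES strings are treated directly as sentences.  The default tokenizer is
atom-aware at the character level: two-letter organic-subset halogens (Cl,
Br) and bracket atoms ([NH4+], [C@@H], ...) are single tokens, every other
character is its own token.  Concatenating a sentence's tokens always
reproduces the input string exactly, so no chemistry engine is needed.

Protein sequences are decomposed into non-overlapping 3-mer "words", either
from reading frame 0 only (``single``) or from all three frames
(``three_frames``), following the ProtVec protocol.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Sentence",
    "Corpus",
    "Vocabulary",
    "tokenize_smiles",
    "tokenize_protein",
    "build_vocab",
    "iter_context_pairs",
]

# bracket atom | two-letter halogen | any single character
_SMILES_TOKEN = re.compile(r"\[[^\[\]]*\]|Cl|Br|.")

FRAME_MODES = ("single", "three_frames")


@dataclass
class Sentence:
    tokens: list[str]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass
class Corpus:
    sentences: list[Sentence]
    kind: str = "smiles"  # {"smiles", "protein"}

    def __post_init__(self) -> None:
        if self.kind not in ("smiles", "protein"):
            raise ValueError(f"unknown corpus kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


class Vocabulary:
    """Dense token dictionary with occurrence counts.

    Indices run 0..|V|-1 ordered by descending corpus count, ties broken
    lexicographically, so a vocabulary built from the same corpus is always
    identical.
    """

    def __init__(self, counts: dict[str, int], min_count: int = 1):
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        kept = {t: c for t, c in counts.items() if c >= min_count}
        if not kept:
            raise ValueError("vocabulary is empty after min_count filtering")
        ordered = sorted(kept, key=lambda t: (-kept[t], t))
        self.min_count = min_count
        self.counts: dict[str, int] = {t: kept[t] for t in ordered}
        self._index: dict[str, int] = {t: i for i, t in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        return self._index[token]

    @property
    def tokens(self) -> list[str]:
        return list(self._index)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Vocabulary)
            and self.counts == other.counts
            and self.min_count == other.min_count
        )


def tokenize_smiles(
    smiles: str, source_id: str = "", granularity: str = "atom"
) -> Sentence:
    """Split a SMILES string into tokens.

    ``granularity="atom"`` keeps Cl/Br and bracket atoms whole;
    ``granularity="char"`` splits every character.  Both modes satisfy the
    round-trip property ``"".join(tokens) == smiles``.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    if granularity not in ("atom", "char"):
        raise ValueError(f"unknown granularity {granularity!r}")
    # bracket balance check (the only structural validation performed)
    depth = 0
    for ch in smiles:
        if ch == "[":
            depth += 1
            if depth > 1:
                raise ValueError(f"malformed SMILES (nested '['): {smiles!r}")
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise ValueError(f"malformed SMILES (unmatched ']'): {smiles!r}")
    if depth != 0:
        raise ValueError(f"malformed SMILES (unclosed '['): {smiles!r}")
    if granularity == "char":
        return Sentence(list(smiles), source_id)
    return Sentence(_SMILES_TOKEN.findall(smiles), source_id)


def tokenize_protein(
    sequence: str, frame_mode: str = "three_frames", source_id: str = ""
) -> list[Sentence]:
    """Decompose a protein sequence into non-overlapping 3-mer sentences.

    Returns one sentence (frame 0) in ``single`` mode, or up to three
    sentences (frames 0, 1, 2) in ``three_frames`` mode.  Trailing residues
    shorter than a full 3-mer are dropped; sequences shorter than three
    residues yield an empty list with a warning.
    """
    if frame_mode not in FRAME_MODES:
        raise ValueError(f"frame_mode must be one of {FRAME_MODES}")
    if not sequence:
        raise ValueError("empty protein sequence")
    if len(sequence) < 3:
        warnings.warn(
            f"sequence {source_id or sequence!r} shorter than 3 residues; no words",
            stacklevel=2,
        )
        return []
    offsets = (0,) if frame_mode == "single" else (0, 1, 2)
    sentences = []
    for off in offsets:
        words = [
            sequence[i : i + 3] for i in range(off, len(sequence) - 2, 3)
        ]
        if words:
            sentences.append(Sentence(words, source_id))
    return sentences


def build_vocab(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Count tokens over a corpus and build the training dictionary."""
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for sentence in corpus:
        for token in sentence:
            counts[token] = counts.get(token, 0) + 1
    return Vocabulary(counts, min_count=min_count)


def iter_context_pairs(
    sentence: Sentence, window: int
) -> list[tuple[str, str]]:
    """Emit all (center, context) token pairs within a fixed symmetric window.

    The context of position i is every position j != i with |i - j| <= window;
    the window is never randomly shrunk, so (a, b) is emitted iff (b, a) is.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens = sentence.tokens
    pairs = []
    for i, center in enumerate(tokens):
        lo = max(0, i - window)
        hi = min(len(tokens), i + window + 1)
        for j in range(lo, hi):
            if j != i:
                pairs.append((center, tokens[j]))
    return pairs
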