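"""Embedding-space analyses: cosine nearest neighbors and 2-D/3-D
projections (t-SNE) colored by per-record property values."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import FeatureBlock

__all__ = [
    "NeighborResult",
    "ProjectedCloud",
    "cosine_distance",
    "top_k_neighbors",
    "project",
    "color_by_property",
]


@dataclass
class NeighborResult:
    query_id: str
    neighbor_ids: list[str]
    distances: list[float]  # cosine distances, ascending

    def __post_init__(self) -> None:
        if len(self.neighbor_ids) != len(self.distances):
            raise ValueError("neighbor ids and distances must align")
        if any(d2 < d1 for d1, d2 in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be ascending")


@dataclass
class ProjectedCloud:
    ids: list[str]
    coordinates: np.ndarray  # n x 2 or n x 3
    colors: np.ndarray | None = None  # per-point scalar in [0, 1]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.ids):
            raise ValueError("coordinates must align with ids")
        if self.coordinates.shape[1] not in (2, 3):
            raise ValueError("projection must be 2-D or 3-D")


def cosine_distance(u, v) -> float:
    """1 - cos(u, v); lies in [0, 2], zero iff the vectors are parallel."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


def top_k_neighbors(block: FeatureBlock, query_id: str, k: int = 10) -> NeighborResult:
    """The k records nearest to the query by cosine distance (exact search).

    The query is excluded from its own list; ties are broken by record id.
    """
    if query_id not in block:
        raise KeyError(f"unknown query id {query_id!r}")
    if k >= len(block.ids):
        raise ValueError("k must be smaller than the number of records")
    q = block.row(query_id)
    scored = [
        (cosine_distance(q, block.row(rid)), rid)
        for rid in block.ids
        if rid != query_id
    ]
    scored.sort()
    top = scored[:k]
    return NeighborResult(
        query_id=query_id,
        neighbor_ids=[rid for _, rid in top],
        distances=[d for d, _ in top],
    )


def project(
    block: FeatureBlock,
    out_dim: int = 2,
    seed: int = 0,
    perplexity: float = 30.0,
) -> ProjectedCloud:
    """t-SNE projection of a feature block into 2 or 3 dimensions.

    Perplexity is capped at (n - 1) / 3 for small inputs; the embedding is
    deterministic given the seed (single-threaded, PCA initialization).
    """
    from sklearn.manifold import TSNE

    if out_dim not in (2, 3):
        raise ValueError("out_dim must be 2 or 3")
    n = len(block.ids)
    if n < 5:
        raise ValueError("too few points to project (need at least 5)")
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(
        n_components=out_dim,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="barnes_hut" if out_dim == 2 else "exact",
    )
    coords = tsne.fit_transform(block.matrix)
    return ProjectedCloud(ids=list(block.ids), coordinates=coords)


def color_by_property(cloud: ProjectedCloud, values) -> ProjectedCloud:
    """Attach min-max-normalized color scalars to a projected cloud.

    Constant inputs map to 0.5 everywhere; normalization is invariant to
    affine transforms of the values.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(cloud.ids):
        raise ValueError("one value per point required")
    lo, hi = values.min(), values.max()
    if hi == lo:
        colors = np.full(len(values), 0.5)
    else:
        colors = (values - lo) / (hi - lo)
    return ProjectedCloud(
        ids=list(cloud.ids), coordinates=cloud.coordinates.copy(), colors=colors
    )
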