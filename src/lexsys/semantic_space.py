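"""Cosine geometry over dense word vectors.

Provides the vector-space container, cosine similarity queries, deterministic
nearest-neighbour retrieval and semantic neighbourhood distance (SND): the
mean cosine distance to a word's m nearest neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SemanticSpace",
    "cosine_similarity",
    "nearest_semantic_neighbors",
    "snd",
    "snd_batch",
]


@dataclass
class SemanticSpace:
    """Vocabulary-aligned dense vectors with cached norms.

    Invariants enforced at construction: no duplicate words, all entries
    finite, every row norm strictly positive.
    """

    vocabulary: list[str]
    vectors: np.ndarray
    norms: np.ndarray = field(init=False, repr=False)
    _index: dict = field(init=False, repr=False)
    _unit: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.vocabulary = list(self.vocabulary)
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError(
                f"vector matrix shape {self.vectors.shape} does not match "
                f"vocabulary of {len(self.vocabulary)} words"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            seen, dups = set(), set()
            for w in self.vocabulary:
                (dups if w in seen else seen).add(w)
            raise ValueError(f"duplicate words in vocabulary: {sorted(dups)[:5]}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("semantic vectors contain NaN or infinite entries")
        self.norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(self.norms == 0):
            bad = [self.vocabulary[i] for i in np.flatnonzero(self.norms == 0)[:5]]
            raise ValueError(f"zero-norm vectors for words: {bad}")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        self._unit = None

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in semantic space") from None

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index(word)]

    @property
    def unit_vectors(self) -> np.ndarray:
        """Row-normalised copy of the vector matrix (cached)."""
        if self._unit is None:
            self._unit = self.vectors / self.norms[:, None]
        return self._unit

    def subset(self, words: Iterable[str]) -> "SemanticSpace":
        words = list(words)
        idx = [self.index(w) for w in words]
        return SemanticSpace(words, self.vectors[idx])


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """cos(u, v) = u.v / (|u||v|), clamped to [-1, 1] against rounding.

    A zero vector is an error, never silently 0.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _cosine_distances_to_all(space: SemanticSpace, i: int) -> np.ndarray:
    sims = space.unit_vectors @ space.unit_vectors[i]
    np.clip(sims, -1.0, 1.0, out=sims)
    return 1.0 - sims


def nearest_semantic_neighbors(
    word: str, space: SemanticSpace, m: int
) -> list[tuple[str, float]]:
    """The m nearest words by cosine distance, ascending, target excluded.

    Ties are broken by vocabulary order (stable sort), so results are
    deterministic for a given space.
    """
    if m < 1:
        raise ValueError("m must be a positive integer")
    if m >= len(space):
        raise ValueError(
            f"m={m} must be smaller than the vocabulary size {len(space)}"
        )
    i = space.index(word)
    dist = _cosine_distances_to_all(space, i)
    dist[i] = np.inf  # exclude the target itself
    order = np.argsort(dist, kind="stable")[:m]
    return [(space.vocabulary[j], float(dist[j])) for j in order]


def snd(word: str, space: SemanticSpace, m: int = 20) -> float:
    """Semantic neighbourhood distance: mean cosine distance of the m nearest
    neighbours. Higher values mean a sparser semantic neighbourhood."""
    neigh = nearest_semantic_neighbors(word, space, m)
    return float(np.mean([d for _, d in neigh]))


def snd_batch(space: SemanticSpace, m: int = 20) -> np.ndarray:
    """SND for every word in the space, vocabulary order."""
    if m >= len(space):
        raise ValueError(
            f"m={m} must be smaller than the vocabulary size {len(space)}"
        )
    unit = space.unit_vectors
    out = np.empty(len(space))
    # row blocks keep the distance matrix small at large vocabularies
    block = max(1, int(2e7) // max(len(space), 1))
    for start in range(0, len(space), block):
        stop = min(start + block, len(space))
        sims = unit[start:stop] @ unit.T
        np.clip(sims, -1.0, 1.0, out=sims)
        dist = 1.0 - sims
        rows = np.arange(start, stop)
        dist[rows - start, rows] = np.inf
        part = np.partition(dist, m - 1, axis=1)[:, :m]
        out[start:stop] = part.mean(axis=1)
    return out
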