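"""Word-form similarity: edit distance, neighbour retrieval, neighbourhood density.

Forms are plain symbol sequences: either orthographic strings or phonological
transcriptions in a one-symbol-per-phoneme encoding. All retrieval schemes are
exhaustive over the candidate lexicon; the heavy one-against-many edit-distance
computation is vectorised with numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NeighborSet",
    "PaddedForms",
    "levenshtein_distance",
    "levenshtein_to_all",
    "embedding_neighbors",
    "kth_distance_neighbors",
    "coltheart_n",
]


@dataclass(frozen=True)
class NeighborSet:
    """Form-based neighbours of a target word.

    ``members`` holds ``(label, distance)`` pairs; the distance is ``None``
    for the embedding scheme, which has no distance notion. ``labels`` are
    whatever the caller supplied (word identifiers or the forms themselves).
    """

    target: str
    method: str  # "embedding" | "kth_distance"
    members: tuple = field(default_factory=tuple)
    k: Optional[int] = None
    fallback_needed: bool = False

    def __post_init__(self):
        if self.method not in ("embedding", "kth_distance"):
            raise ValueError(f"unknown neighbour method {self.method!r}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list:
        return [m[0] for m in self.members]

    @property
    def distances(self) -> list:
        return [m[1] for m in self.members]


def levenshtein_distance(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions).

    Works on strings or on arbitrary symbol sequences. Empty inputs are
    allowed; the distance to an empty sequence is the other's length.
    """
    if len(a) < len(b):
        a, b = b, a
    if len(b) == 0:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class _SymbolCodec:
    """Maps hashable symbols to small ints for the vectorised DP."""

    def __init__(self):
        self._table: dict = {}

    def encode(self, form: Sequence) -> np.ndarray:
        t = self._table
        out = np.empty(len(form), dtype=np.int32)
        for i, s in enumerate(form):
            code = t.get(s)
            if code is None:
                code = len(t)
                t[s] = code
            out[i] = code
        return out


def _pad_forms(forms: Sequence[Sequence], codec: _SymbolCodec):
    n = len(forms)
    lengths = np.fromiter((len(f) for f in forms), dtype=np.int64, count=n)
    lmax = int(lengths.max()) if n else 0
    mat = np.full((n, lmax), -1, dtype=np.int32)
    for i, f in enumerate(forms):
        mat[i, : lengths[i]] = codec.encode(f)
    return mat, lengths


def _distances_to_padded(
    t: np.ndarray, mat: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """One-against-many Wagner-Fischer over pre-encoded, padded candidates.

    The horizontal (insertion) dependency is resolved with a running-minimum
    pass so every DP step is vectorised over all candidates at once.
    """
    n, lmax = mat.shape
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if lmax == 0:
        return np.full(n, len(t), dtype=np.int64)
    js = np.arange(lmax + 1, dtype=np.int32)
    row = np.broadcast_to(js, (n, lmax + 1)).copy()
    best = np.empty_like(row)
    for i in range(1, len(t) + 1):
        cost = (mat != t[i - 1]).astype(np.int32)
        best[:, 0] = i
        np.minimum(row[:, 1:] + 1, row[:, :-1] + cost, out=best[:, 1:])
        # d[i][j] = j + min_{k<=j} (best[k] - k): resolves insertions left-to-right
        row = js + np.minimum.accumulate(best - js, axis=1)
    return row[np.arange(n), lengths].astype(np.int64)


class PaddedForms:
    """A lexicon of forms encoded once for repeated one-against-many queries."""

    def __init__(self, forms: Sequence[Sequence]):
        self.forms = list(forms)
        self._codec = _SymbolCodec()
        self._mat, self._lengths = _pad_forms(self.forms, self._codec)

    def __len__(self) -> int:
        return len(self.forms)

    def distances_from(self, target: Sequence) -> np.ndarray:
        """Edit distance from ``target`` to every stored form."""
        return _distances_to_padded(
            self._codec.encode(target), self._mat, self._lengths
        )


def levenshtein_to_all(target: Sequence, forms: Sequence[Sequence]) -> np.ndarray:
    """Edit distance from ``target`` to every form, as an int array."""
    return PaddedForms(forms).distances_from(target)


def embedding_neighbors(
    target: str,
    lexicon: Sequence[str],
    labels: Optional[Sequence] = None,
) -> NeighborSet:
    """All lexicon forms that strictly contain ``target`` as a contiguous substring.

    Forms identical to the target are never members (containment must be
    strict, so members are strictly longer). ``fallback_needed`` is set when
    no form embeds the target.
    """
    if labels is None:
        labels = lexicon
    members = tuple(
        (lab, None)
        for form, lab in zip(lexicon, labels)
        if len(form) > len(target) and target in form
    )
    return NeighborSet(
        target=target,
        method="embedding",
        members=members,
        fallback_needed=not members,
    )


def kth_distance_neighbors(
    target: str,
    lexicon: Sequence[str],
    k: int = 5,
    labels: Optional[Sequence] = None,
) -> NeighborSet:
    """All lexicon forms within the distance of the k-th nearest one.

    Let d* be the k-th smallest edit distance from the target to the candidate
    forms; every form at distance <= d* is a member (tie-inclusive, no
    sampling). Homophones/homographs of the target (distance 0) are excluded
    so downstream inverse-distance weights stay defined. The caller must not
    include the target word itself among the candidates.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if labels is None:
        labels = lexicon
    dists = levenshtein_to_all(target, lexicon)
    keep = dists >= 1
    n_candidates = int(keep.sum())
    if n_candidates < k:
        raise ValueError(
            f"need at least k={k} candidate forms at distance >= 1, "
            f"found {n_candidates} in a lexicon of {len(lexicon)}"
        )
    kept = dists[keep]
    dstar = int(np.partition(kept, k - 1)[k - 1])
    members = tuple(
        (lab, int(d))
        for lab, d, ok in zip(labels, dists, keep)
        if ok and d <= dstar
    )
    return NeighborSet(target=target, method="kth_distance", members=members, k=k)


def coltheart_n(
    target: Sequence,
    lexicon: Sequence[Sequence],
    mode: str = "substitution",
) -> int:
    """Phonological neighbourhood density of ``target`` over ``lexicon``.

    ``substitution`` counts forms obtainable by changing exactly one symbol
    (same length, Hamming distance 1). ``das`` counts every form at edit
    distance 1 (additions, deletions and substitutions). The target itself
    (distance 0) never counts.
    """
    if mode not in ("substitution", "das"):
        raise ValueError(f"unknown PND mode {mode!r}")
    if len(lexicon) == 0:
        return 0
    if mode == "substitution":
        m = len(target)
        count = 0
        for form in lexicon:
            if len(form) != m:
                continue
            mismatch = sum(1 for x, y in zip(target, form) if x != y)
            if mismatch == 1:
                count += 1
        return count
    dists = levenshtein_to_all(target, lexicon)
    return int(np.sum(dists == 1))
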