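"""Form-to-semantics consistency (FSC) scores and their robustness baselines.

Two variants:

- ``te`` (target-embedding): neighbours are lexicon words whose form strictly
  contains the target's form; cosines to the target's vector are weighted by
  neighbour corpus frequency. When no word embeds the target, 20 words are
  sampled uniformly from the reference lexicon as stand-in neighbours.
- ``ld`` (edit-distance): neighbours are all words within the distance of the
  k-th nearest form (tie-inclusive, k defaults to 5); cosines are weighted by
  inverse edit distance. The printed normaliser is ambiguous between the
  neighbour count N ("literal") and the weight sum ("weight_sum"); both are
  implemented and every score records which was used.

Both variants run over phonological or orthographic encodings (PSC vs OSC).
The module also implements the scrambled form-meaning permutation baseline
and reference-lexicon subsampling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import aoa_inference
from .form_space import NeighborSet, PaddedForms, coltheart_n
from .lexicon_io import LexEntry
from .semantic_space import SemanticSpace, cosine_similarity, snd_batch

__all__ = [
    "FSCScore",
    "PermutationRun",
    "SubsampleRun",
    "fsc_te",
    "fsc_ld",
    "fsc_batch",
    "permuted_fsc_baseline",
    "subsampled_fsc",
    "build_study_table",
]

_FALLBACK_SAMPLE = 20
_FALLBACK_TAG = 606
_PERMUTE_TAG = 707
_SUBSAMPLE_TAG = 808


@dataclass(frozen=True)
class FSCScore:
    word: str
    value: float
    method: str  # "te" | "ld"
    encoding: str  # "phonological" | "orthographic"
    n_neighbors: int
    fallback_used: bool = False
    normalization: Optional[str] = None  # "literal" | "weight_sum" (ld only)

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"FSC value {self.value} outside [-1, 1]")
        if self.fallback_used and self.method != "te":
            raise ValueError("the random-neighbour fallback only applies to method='te'")


def fsc_te(
    target: str,
    neighbors: NeighborSet,
    space: SemanticSpace,
    frequencies: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
    reference: Optional[Sequence[str]] = None,
    encoding: str = "phonological",
) -> FSCScore:
    """Frequency-weighted mean cosine between the target and its embedding
    neighbours: ``sum_i cos(t, n_i) f_i / sum_i f_i``.

    With an empty neighbour set, 20 reference-lexicon words (target excluded)
    are drawn uniformly without replacement via ``rng`` and used instead,
    still frequency-weighted.
    """
    labels = neighbors.labels
    fallback = False
    if not labels:
        if rng is None or reference is None:
            raise ValueError(
                f"no embedding neighbours for {target!r}: the fallback needs "
                "an rng and a reference word list"
            )
        pool = [w for w in reference if w != target]
        if len(pool) < _FALLBACK_SAMPLE:
            raise ValueError(
                f"reference lexicon too small for the {_FALLBACK_SAMPLE}-word fallback"
            )
        labels = list(rng.choice(np.array(pool, dtype=object), _FALLBACK_SAMPLE, replace=False))
        fallback = True
    tvec = space.vector(target)
    num = 0.0
    den = 0.0
    for w in labels:
        if w not in space:
            raise ValueError(f"neighbour {w!r} of {target!r} has no semantic vector")
        if w not in frequencies:
            raise ValueError(f"neighbour {w!r} of {target!r} has no frequency")
        f = float(frequencies[w])
        num += cosine_similarity(tvec, space.vector(w)) * f
        den += f
    value = float(np.clip(num / den, -1.0, 1.0))
    return FSCScore(
        word=target,
        value=value,
        method="te",
        encoding=encoding,
        n_neighbors=len(labels),
        fallback_used=fallback,
    )


def fsc_ld(
    target: str,
    neighbors: NeighborSet,
    space: SemanticSpace,
    normalization: str = "literal",
    encoding: str = "phonological",
) -> FSCScore:
    """Inverse-distance-weighted consistency over k-th-distance neighbours.

    literal:    ``sum_i cos(t, n_i) / d_i / N``
    weight_sum: ``sum_i cos(t, n_i) / d_i / sum_i (1 / d_i)``
    """
    if normalization not in ("literal", "weight_sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if len(neighbors) == 0:
        raise ValueError(f"empty neighbour set for {target!r}")
    tvec = space.vector(target)
    num = 0.0
    wsum = 0.0
    for w, d in neighbors.members:
        if d is None or d < 1:
            raise ValueError(
                f"neighbour {w!r} of {target!r} has distance {d}; "
                "homophones must be excluded upstream"
            )
        weight = 1.0 / d
        num += cosine_similarity(tvec, space.vector(w)) * weight
        wsum += weight
    den = len(neighbors) if normalization == "literal" else wsum
    value = float(np.clip(num / den, -1.0, 1.0))
    return FSCScore(
        word=target,
        value=value,
        method="ld",
        encoding=encoding,
        n_neighbors=len(neighbors),
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# batch machinery: neighbour retrieval is done once; scores are then linear
# in the cosine matrix, so permutation baselines reuse the cached structure.


@dataclass
class _ScoreStructure:
    """Per-target neighbour indices and weights, resolved against a space."""

    words: list[str]
    target_idx: np.ndarray
    flat_targets: np.ndarray  # target space-index repeated per neighbour pair
    flat_neighbors: np.ndarray
    flat_weights: np.ndarray
    segments: np.ndarray  # target row id per pair, for bincount reduction
    denom: np.ndarray
    n_neighbors: np.ndarray
    fallback: np.ndarray


def _forms_for(entries: Sequence[LexEntry], encoding: str) -> list[str]:
    if encoding == "phonological":
        return [e.phoneme_string for e in entries]
    if encoding == "orthographic":
        return [e.word for e in entries]
    raise ValueError(f"unknown encoding {encoding!r}")


def _target_form(row, encoding: str) -> str:
    return str(row["phonemes"]) if encoding == "phonological" else str(row["word"])


def _retrieve_structure(
    study: pd.DataFrame,
    lexicon: Sequence[LexEntry],
    space: SemanticSpace,
    method: str,
    encoding: str,
    k: int,
    seed: int,
    normalization: str,
) -> _ScoreStructure:
    lex_forms = _forms_for(lexicon, encoding)
    lex_words = [e.word for e in lexicon]
    lex_words_arr = np.array(lex_words, dtype=object)
    freqs = np.array([e.frequency for e in lexicon], dtype=np.float64)
    padded = PaddedForms(lex_forms) if method == "ld" else None
    rng = np.random.default_rng([_FALLBACK_TAG, seed])

    targets = list(study["word"].astype(str))
    target_idx = np.array([space.index(w) for w in targets], dtype=np.int64)

    flat_t: list[int] = []
    flat_n: list[int] = []
    flat_w: list[float] = []
    segments: list[int] = []
    denom = np.empty(len(targets))
    n_neighbors = np.zeros(len(targets), dtype=np.int64)
    fallback = np.zeros(len(targets), dtype=bool)

    for row_id, (_, row) in enumerate(study.iterrows()):
        word = str(row["word"])
        tform = _target_form(row, encoding)
        if method == "te":
            idx = [
                j
                for j, form in enumerate(lex_forms)
                if lex_words[j] != word and len(form) > len(tform) and tform in form
            ]
            if idx:
                weights = freqs[idx]
            else:
                pool = [j for j, w in enumerate(lex_words) if w != word]
                if len(pool) < _FALLBACK_SAMPLE:
                    raise ValueError(
                        f"reference lexicon too small for the fallback at {word!r}"
                    )
                idx = list(rng.choice(pool, _FALLBACK_SAMPLE, replace=False))
                weights = freqs[idx]
                fallback[row_id] = True
            d = float(weights.sum())
        elif method == "ld":
            dists = padded.distances_from(tform)
            # homophones/homographs (d = 0) and the target itself excluded
            keep = (dists >= 1) & (lex_words_arr != word)
            n_ok = int(keep.sum())
            if n_ok < k:
                raise ValueError(
                    f"target {word!r} has only {n_ok} candidates at distance "
                    f">= 1 for k={k} (lexicon size {len(lexicon)})"
                )
            dstar = int(np.partition(dists[keep], k - 1)[k - 1])
            sel = np.flatnonzero(keep & (dists <= dstar))
            idx = list(sel)
            weights = 1.0 / dists[sel]
            d = float(len(idx)) if normalization == "literal" else float(weights.sum())
        else:
            raise ValueError(f"unknown method {method!r}")

        space_idx = [space.index(lex_words[j]) for j in idx]
        flat_t.extend([target_idx[row_id]] * len(idx))
        flat_n.extend(space_idx)
        flat_w.extend(np.asarray(weights, dtype=np.float64))
        segments.extend([row_id] * len(idx))
        denom[row_id] = d
        n_neighbors[row_id] = len(idx)

    return _ScoreStructure(
        words=targets,
        target_idx=target_idx,
        flat_targets=np.array(flat_t, dtype=np.int64),
        flat_neighbors=np.array(flat_n, dtype=np.int64),
        flat_weights=np.array(flat_w, dtype=np.float64),
        segments=np.array(segments, dtype=np.int64),
        denom=denom,
        n_neighbors=n_neighbors,
        fallback=fallback,
    )


def _scores_from_structure(
    structure: _ScoreStructure,
    unit_vectors: np.ndarray,
    permutation: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Evaluate scores under an optional permutation of the word->vector map."""
    u = unit_vectors if permutation is None else unit_vectors[permutation]
    cos = np.einsum(
        "ij,ij->i", u[structure.flat_targets], u[structure.flat_neighbors]
    )
    np.clip(cos, -1.0, 1.0, out=cos)
    sums = np.bincount(
        structure.segments,
        weights=cos * structure.flat_weights,
        minlength=len(structure.words),
    )
    return np.clip(sums / structure.denom, -1.0, 1.0)


def fsc_batch(
    study: pd.DataFrame,
    lexicon: Sequence[LexEntry],
    space: SemanticSpace,
    method: str = "ld",
    encoding: str = "phonological",
    k: int = 5,
    seed: int = 0,
    normalization: str = "literal",
    column: Optional[str] = None,
    pnd_mode: str = "substitution",
) -> tuple[pd.DataFrame, dict]:
    """Score every study word; returns ``(table_with_column, run_manifest)``.

    The output column defaults to ``fsc_<method>``. The manifest records
    every knob needed to reproduce the run.
    """
    structure = _retrieve_structure(
        study, lexicon, space, method, encoding, k, seed, normalization
    )
    values = _scores_from_structure(structure, space.unit_vectors)
    column = column or f"fsc_{method}"
    out = study.copy()
    out[column] = values
    manifest = {
        "column": column,
        "method": method,
        "encoding": encoding,
        "k": k,
        "normalization": normalization if method == "ld" else None,
        "pnd_mode": pnd_mode,
        "seed": seed,
        "n_targets": len(structure.words),
        "n_fallback": int(structure.fallback.sum()),
        "reference_size": len(lexicon),
    }
    return out, manifest


@dataclass
class PermutationRun:
    """Distribution of score/AoA association under scrambled form-meaning maps."""

    n_iterations: int
    seed: int
    correlations: np.ndarray
    delta_aics: np.ndarray
    true_correlation: float
    true_delta_aic: float

    def summary(self) -> dict:
        pct = np.percentile(self.delta_aics, [2.5, 5, 50, 95, 97.5])
        return {
            "corr_mean": float(self.correlations.mean()),
            "corr_sd": float(self.correlations.std(ddof=1)),
            "delta_aic_mean": float(self.delta_aics.mean()),
            "delta_aic_sd": float(self.delta_aics.std(ddof=1)),
            "delta_aic_percentiles": {
                "2.5": float(pct[0]),
                "5": float(pct[1]),
                "50": float(pct[2]),
                "95": float(pct[3]),
                "97.5": float(pct[4]),
            },
            "true_correlation": self.true_correlation,
            "true_delta_aic": self.true_delta_aic,
        }


def _delta_aic_for_scores(
    table: pd.DataFrame,
    scores: np.ndarray,
    baseline_predictors: Sequence[str],
    response: str,
    transform: bool,
) -> float:
    work = table.copy()
    work["_score"] = scores
    if transform:
        work, _ = aoa_inference.boxcox_z(work, ["_score"])
    base = aoa_inference.fit_linear(work, response, list(baseline_predictors))
    aug = aoa_inference.fit_linear(
        work, response, list(baseline_predictors) + ["_score"]
    )
    return aoa_inference.compare(base, aug).delta_aic


def permuted_fsc_baseline(
    study: pd.DataFrame,
    lexicon: Sequence[LexEntry],
    space: SemanticSpace,
    baseline_predictors: Sequence[str],
    response: str = "aoa",
    method: str = "ld",
    encoding: str = "phonological",
    k: int = 5,
    normalization: str = "literal",
    n_iterations: int = 1000,
    seed: int = 0,
    transform_scores: bool = True,
) -> PermutationRun:
    """Scramble the word->vector assignment ``n_iterations`` times.

    Each iteration permutes the semantic space (neighbourhood structure in
    both form and semantic space is untouched; only which word points to
    which vector changes), recomputes the FSC column, and records its Pearson
    correlation with the response plus the delta-AIC of the baseline model
    augmented with the (transformed) score. The unpermuted mapping's numbers
    are returned alongside for calibration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    structure = _retrieve_structure(
        study, lexicon, space, method, encoding, k, seed, normalization
    )
    unit = space.unit_vectors
    y = study[response].to_numpy(dtype=np.float64)

    true_scores = _scores_from_structure(structure, unit)
    true_corr = float(np.corrcoef(true_scores, y)[0, 1])
    true_delta = _delta_aic_for_scores(
        study, true_scores, baseline_predictors, response, transform_scores
    )

    corrs = np.empty(n_iterations)
    deltas = np.empty(n_iterations)
    for i in range(n_iterations):
        rng = np.random.default_rng([_PERMUTE_TAG, seed, i])
        perm = rng.permutation(len(space))
        scores = _scores_from_structure(structure, unit, permutation=perm)
        corrs[i] = np.corrcoef(scores, y)[0, 1]
        deltas[i] = _delta_aic_for_scores(
            study, scores, baseline_predictors, response, transform_scores
        )
    return PermutationRun(
        n_iterations=n_iterations,
        seed=seed,
        correlations=corrs,
        delta_aics=deltas,
        true_correlation=true_corr,
        true_delta_aic=true_delta,
    )


@dataclass
class SubsampleRun:
    rate: float
    n_iterations: int
    seed: int
    scores: pd.DataFrame  # one row per iteration, one column per study word
    delta_aics: np.ndarray
    n_excluded: np.ndarray  # study words dropped per iteration (< k candidates)

    def summary(self) -> dict:
        return {
            "rate": self.rate,
            "delta_aic_mean": float(np.nanmean(self.delta_aics)),
            "delta_aic_sd": float(np.nanstd(self.delta_aics, ddof=1)),
            "mean_excluded": float(self.n_excluded.mean()),
        }


def subsampled_fsc(
    study: pd.DataFrame,
    lexicon: Sequence[LexEntry],
    space: SemanticSpace,
    baseline_predictors: Sequence[str],
    response: str = "aoa",
    method: str = "ld",
    encoding: str = "phonological",
    k: int = 5,
    normalization: str = "literal",
    rate: float = 0.75,
    n_iterations: int = 500,
    seed: int = 0,
    transform_scores: bool = True,
) -> SubsampleRun:
    """Recompute FSC with neighbours drawn from random sub-lexicons.

    Each iteration samples ``floor(rate * V)`` reference entries without
    replacement, retrieves neighbours within the subset only, rescore and
    records the delta-AIC against the baseline model. Study words left with
    fewer than ``k`` candidates in a draw are excluded from that iteration
    (scores NaN) and counted in ``n_excluded``.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must lie in (0, 1]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_sub = int(np.floor(rate * len(lexicon)))
    words = list(study["word"].astype(str))
    all_scores = np.full((n_iterations, len(words)), np.nan)
    deltas = np.full(n_iterations, np.nan)
    n_excluded = np.zeros(n_iterations, dtype=np.int64)

    for i in range(n_iterations):
        rng = np.random.default_rng([_SUBSAMPLE_TAG, seed, i])
        if rate == 1.0:
            sub = list(lexicon)
        else:
            pick = rng.choice(len(lexicon), n_sub, replace=False)
            sub = [lexicon[j] for j in sorted(pick)]
        try:
            structure = _retrieve_structure(
                study, sub, space, method, encoding, k, seed, normalization
            )
            scores = _scores_from_structure(structure, space.unit_vectors)
            keep = np.ones(len(words), dtype=bool)
        except ValueError:
            # some word fell under k candidates: redo row by row, flagging them
            scores = np.full(len(words), np.nan)
            keep = np.zeros(len(words), dtype=bool)
            for row_id in range(len(words)):
                one = study.iloc[[row_id]]
                try:
                    st = _retrieve_structure(
                        one, sub, space, method, encoding, k, seed, normalization
                    )
                except ValueError:
                    continue
                scores[row_id] = _scores_from_structure(st, space.unit_vectors)[0]
                keep[row_id] = True
        n_excluded[i] = int((~keep).sum())
        all_scores[i] = scores
        subset = study.loc[keep].copy()
        deltas[i] = _delta_aic_for_scores(
            subset,
            scores[keep],
            baseline_predictors,
            response,
            transform_scores,
        )
    return SubsampleRun(
        rate=rate,
        n_iterations=n_iterations,
        seed=seed,
        scores=pd.DataFrame(all_scores, columns=words),
        delta_aics=deltas,
        n_excluded=n_excluded,
    )


def _pnd_batch(forms: Sequence[tuple], mode: str) -> np.ndarray:
    """Coltheart's N for every form at once (equal to per-word coltheart_n)."""
    if mode != "substitution":
        return np.array(
            [
                coltheart_n(f, forms[:i] + forms[i + 1 :], mode=mode)
                for i, f in enumerate(forms)
            ],
            dtype=np.int64,
        )
    # substitution mode: pairwise Hamming within equal-length groups
    codes: dict = {}
    encoded = []
    for f in forms:
        encoded.append([codes.setdefault(s, len(codes)) for s in f])
    by_length: dict[int, list[int]] = defaultdict(list)
    for i, f in enumerate(encoded):
        by_length[len(f)].append(i)
    out = np.zeros(len(forms), dtype=np.int64)
    for length, idx in by_length.items():
        if len(idx) < 2:
            continue
        mat = np.array([encoded[i] for i in idx], dtype=np.int32)
        mism = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        out[idx] = (mism == 1).sum(axis=1)
    return out


def build_study_table(
    lexicon,
    k: int = 5,
    snd_m: int = 20,
    pnd_mode: str = "substitution",
    seed: int = 0,
    normalization: str = "literal",
    encoding: str = "phonological",
    methods: Sequence[str] = ("te", "ld"),
) -> tuple[pd.DataFrame, dict]:
    """Assemble the full analysis table for a synthetic lexicon.

    Computes PND (Coltheart's N), SND and the requested FSC columns over the
    lexicon's own entries, joined with its covariates (and AoA when already
    generated). Convenience for simulations and tests.
    """
    entries = lexicon.entries
    space = lexicon.space
    study = lexicon.covariates.copy()
    study["phonemes"] = [e.phoneme_string for e in entries]
    study["frequency"] = [e.frequency for e in entries]

    study["pnd"] = _pnd_batch([e.phonemes for e in entries], pnd_mode)
    study["snd"] = snd_batch(space, m=snd_m)

    manifest = {"k": k, "snd_m": snd_m, "pnd_mode": pnd_mode, "seed": seed}
    for method in methods:
        study, m = fsc_batch(
            study,
            entries,
            space,
            method=method,
            encoding=encoding,
            k=k,
            seed=seed,
            normalization=normalization,
        )
        manifest[f"fsc_{method}"] = m
    if lexicon.aoa is not None:
        study["aoa"] = lexicon.aoa.to_numpy()
    return study, manifest
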