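"""Synthetic lexicons with controllable form-meaning structure.

Generates phoneme-string word forms over a small inventory, Zipf-distributed
integer frequencies, unit-norm semantic vectors whose form-derived signal
fraction is a dial (``systematicity``), independent covariates, and — in a
second phase — an age-of-acquisition column from a stated linear model.

The semantic construction: each form is featurised as a boundary-marked
character-bigram count vector, projected through a fixed Gaussian matrix
(seeded independently of word sampling) and normalised, giving f(form);
the word's vector is ``normalize(s * f(form) + (1 - s) * g)`` with ``g`` an
independent unit-norm Gaussian draw and ``s`` the systematicity dial. At
``s = 1`` the vector is a deterministic function of the form alone; at
``s = 0`` form and meaning are unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon_io import LexEntry
from .semantic_space import SemanticSpace

__all__ = ["SyntheticConfig", "SyntheticLexicon", "generate_lexicon", "generate_aoa"]

# independent stream tags so word sampling, projection, covariates and noise
# never share draws
_PROJECTION_TAG = 101
_FORMS_TAG = 202
_VECTOR_TAG = 303
_COVARIATE_TAG = 404
_AOA_TAG = 505

DEFAULT_COVARIATE_PARAMS: Mapping[str, float] = {
    "concreteness_mean": 3.0,
    "concreteness_sd": 1.0,
    "valence_mean": 5.0,
    "valence_sd": 1.5,
    "iconicity_mean": 0.0,
    "iconicity_sd": 1.0,
    "morph_p": 0.3,
}


@dataclass(frozen=True)
class SyntheticConfig:
    vocab_size: int = 1000
    phoneme_inventory: tuple = tuple("ptkbdgmnszaeiou")
    length_range: tuple = (3, 7)
    zipf_exponent: float = 1.0
    vector_dim: int = 50
    systematicity: float = 0.5
    covariate_params: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    aoa_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": 8.0}
    )
    aoa_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        inv = tuple(self.phoneme_inventory)
        if len(set(inv)) != len(inv):
            raise ValueError("phoneme inventory symbols must be unique")
        if any(len(str(s)) != 1 for s in inv):
            raise ValueError("phoneme symbols must be single characters")
        if "#" in inv:
            raise ValueError("'#' is reserved as the form boundary marker")
        object.__setattr__(self, "phoneme_inventory", inv)
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        object.__setattr__(self, "length_range", (int(lo), int(hi)))
        if not 0.0 <= self.systematicity <= 1.0:
            raise ValueError("systematicity must lie in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.vector_dim < 1:
            raise ValueError("vector_dim must be a positive integer")
        if self.aoa_noise_sd < 0:
            raise ValueError("aoa_noise_sd must be non-negative")
        if "intercept" not in self.aoa_coefficients:
            raise ValueError("aoa_coefficients must include an 'intercept' entry")

    @property
    def form_capacity(self) -> int:
        lo, hi = self.length_range
        a = len(self.phoneme_inventory)
        return sum(a**length for length in range(lo, hi + 1))


@dataclass
class SyntheticLexicon:
    entries: list[LexEntry]
    space: SemanticSpace
    covariates: pd.DataFrame
    config: SyntheticConfig
    aoa: Optional[pd.Series] = None

    @property
    def words(self) -> list[str]:
        return [e.word for e in self.entries]

    def phonology(self) -> dict[str, tuple]:
        return {e.word: e.phonemes for e in self.entries}

    def frequencies(self) -> dict[str, int]:
        return {e.word: e.frequency for e in self.entries}


def _bigram_index(inventory: Sequence[str]) -> dict[tuple, int]:
    symbols = sorted(inventory) + ["#"]
    return {
        (a, b): i
        for i, (a, b) in enumerate(
            (a, b) for a in symbols for b in symbols
        )
    }


def _bigram_counts(form: str, index: Mapping[tuple, int]) -> np.ndarray:
    out = np.zeros(len(index))
    padded = "#" + form + "#"
    for a, b in zip(padded, padded[1:]):
        out[index[(a, b)]] += 1.0
    return out


def form_feature_vectors(
    forms: Sequence[str], config: SyntheticConfig
) -> np.ndarray:
    """Unit-norm form features: bigram counts through the fixed projection.

    The projection depends only on the config seed and the inventory, never
    on which words were sampled, so a given form always maps to the same
    feature vector under a given config.
    """
    index = _bigram_index(config.phoneme_inventory)
    rng = np.random.default_rng([_PROJECTION_TAG, config.seed])
    projection = rng.standard_normal((len(index), config.vector_dim))
    counts = np.stack([_bigram_counts(f, index) for f in forms])
    feats = counts @ projection
    norms = np.linalg.norm(feats, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate zero-norm form feature vector")
    return feats / norms


def _sample_forms(config: SyntheticConfig) -> list[str]:
    if config.vocab_size > config.form_capacity:
        raise ValueError(
            f"vocab_size={config.vocab_size} exceeds the {config.form_capacity} "
            f"distinct forms available with {len(config.phoneme_inventory)} "
            f"phonemes at lengths {config.length_range}"
        )
    rng = np.random.default_rng([_FORMS_TAG, config.seed])
    lo, hi = config.length_range
    inv = np.array(config.phoneme_inventory)
    forms: list[str] = []
    seen: set[str] = set()
    while len(forms) < config.vocab_size:
        length = int(rng.integers(lo, hi + 1))
        form = "".join(rng.choice(inv, size=length))
        if form not in seen:
            seen.add(form)
            forms.append(form)
    return forms


def _zipf_frequencies(config: SyntheticConfig) -> np.ndarray:
    # counts ~ rank^-a, scaled so the rarest word still gets ~10 tokens: keeps
    # the log-log rank-frequency slope close to -a despite integer rounding
    ranks = np.arange(1, config.vocab_size + 1, dtype=np.float64)
    counts = np.round(10.0 * (config.vocab_size / ranks) ** config.zipf_exponent)
    return np.maximum(counts, 1).astype(np.int64)


def generate_lexicon(config: SyntheticConfig) -> SyntheticLexicon:
    """Deterministically generate a lexicon from the config (same seed, same bits)."""
    forms = _sample_forms(config)
    freqs = _zipf_frequencies(config)

    feats = form_feature_vectors(forms, config)
    rng_vec = np.random.default_rng([_VECTOR_TAG, config.seed])
    noise = rng_vec.standard_normal((config.vocab_size, config.vector_dim))
    noise /= np.linalg.norm(noise, axis=1, keepdims=True)
    s = config.systematicity
    mixed = s * feats + (1.0 - s) * noise
    norms = np.linalg.norm(mixed, axis=1, keepdims=True)
    if np.any(norms == 0):  # can only happen by measure-zero cancellation
        raise ValueError("degenerate zero-norm semantic vector; change the seed")
    vectors = mixed / norms

    params = dict(DEFAULT_COVARIATE_PARAMS)
    params.update(config.covariate_params)
    rng_cov = np.random.default_rng([_COVARIATE_TAG, config.seed])
    n = config.vocab_size
    covariates = pd.DataFrame(
        {
            "word": forms,
            "concreteness": rng_cov.normal(
                params["concreteness_mean"], params["concreteness_sd"], n
            ),
            "valence": rng_cov.normal(params["valence_mean"], params["valence_sd"], n),
            "iconicity": rng_cov.normal(
                params["iconicity_mean"], params["iconicity_sd"], n
            ),
            "morph_complex": (rng_cov.random(n) < params["morph_p"]).astype(int),
            "length_phonemes": [len(f) for f in forms],
        }
    )

    entries = [
        LexEntry(word=f, phonemes=tuple(f), frequency=int(c))
        for f, c in zip(forms, freqs)
    ]
    space = SemanticSpace(forms, vectors)
    return SyntheticLexicon(entries=entries, space=space, covariates=covariates, config=config)


def generate_aoa(
    lexicon: SyntheticLexicon,
    predictors: pd.DataFrame,
    config: Optional[SyntheticConfig] = None,
    min_value: Optional[float] = None,
) -> SyntheticLexicon:
    """Fill in AoA from the configured linear model over ``predictors``.

    ``aoa_i = intercept + sum_k beta_k * x_ik + Normal(0, aoa_noise_sd)``.
    Rows of ``predictors`` must align with the lexicon entries. When
    ``min_value`` is given the result is shifted (affinely, slope 1) so its
    minimum equals it — correlation structure is unchanged.
    """
    config = config or lexicon.config
    coeffs = dict(config.aoa_coefficients)
    intercept = coeffs.pop("intercept")
    missing = [name for name in coeffs if name not in predictors.columns]
    if missing:
        raise ValueError(
            f"aoa_coefficients name predictor columns that are missing: {missing}"
        )
    if len(predictors) != len(lexicon.entries):
        raise ValueError(
            f"predictor table has {len(predictors)} rows for "
            f"{len(lexicon.entries)} lexicon entries"
        )
    values = np.full(len(predictors), float(intercept))
    for name, beta in coeffs.items():
        values = values + float(beta) * predictors[name].to_numpy(dtype=np.float64)
    if config.aoa_noise_sd > 0:
        rng = np.random.default_rng([_AOA_TAG, config.seed])
        values = values + rng.normal(0.0, config.aoa_noise_sd, len(values))
    if min_value is not None:
        values = values - values.min() + min_value
    out = replace_aoa(lexicon, pd.Series(values, name="aoa"))
    return out


def replace_aoa(lexicon: SyntheticLexicon, aoa: pd.Series) -> SyntheticLexicon:
    return SyntheticLexicon(
        entries=lexicon.entries,
        space=lexicon.space,
        covariates=lexicon.covariates,
        config=lexicon.config,
        aoa=aoa.reset_index(drop=True),
    )
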