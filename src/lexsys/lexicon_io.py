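"""Readers/writers for lexical resources and study-table assembly.

Three formats are supported: delimited norms tables (CSV/TSV with a header),
two-column phonological lexicons (word<TAB>transcription, one character per
phoneme), and the standard word-embedding text format (``<vocab> <dim>``
header followed by one word plus ``dim`` reals per line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .semantic_space import SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "LexEntry",
    "read_tabular_norms",
    "write_tabular_norms",
    "read_phonological_lexicon",
    "write_phonological_lexicon",
    "read_semantic_vectors",
    "write_semantic_vectors",
    "assemble_study_lexicon",
    "write_study_table",
    "STUDY_COLUMNS",
]

#: Fixed column order for exported study tables. FSC columns are appended
#: after these in the order they were computed.
STUDY_COLUMNS = [
    "word",
    "phonemes",
    "aoa",
    "frequency",
    "concreteness",
    "valence",
    "iconicity",
    "morph_complex",
    "length_phonemes",
]

#: Canonical norms column names a column map may target.
NORMS_FIELDS = [
    "word",
    "aoa",
    "concreteness",
    "valence",
    "iconicity",
    "morph_complex",
    "length_phonemes",
]


@dataclass(frozen=True)
class LexEntry:
    """One reference-lexicon item: orthographic form, phonemes, corpus count."""

    word: str
    phonemes: tuple
    frequency: int

    def __post_init__(self):
        if not self.word:
            raise ValueError("word must be non-empty")
        if not self.phonemes:
            raise ValueError(f"phoneme sequence for {self.word!r} must be non-empty")
        if self.frequency < 1:
            raise ValueError(
                f"frequency for {self.word!r} must be >= 1, got {self.frequency}"
            )

    @property
    def phoneme_string(self) -> str:
        return "".join(self.phonemes)


def read_tabular_norms(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited norms table into canonical columns.

    ``column_map`` maps canonical field names (see ``NORMS_FIELDS``) to the
    column names in the file; unmapped canonical fields are taken verbatim
    when a same-named column exists, and extra file columns are ignored.
    Missing cells stay missing (NaN), never zero. Duplicate word rows (e.g.
    one per word sense) pass through untouched; the study-assembly step
    reduces them.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    column_map = dict(column_map or {})
    for canonical, source in column_map.items():
        if source not in df.columns:
            raise ValueError(
                f"column map names {source!r} for field {canonical!r}, "
                f"but the file only has columns {list(df.columns)}"
            )
    rename = {src: canon for canon, src in column_map.items()}
    df = df.rename(columns=rename)
    keep = [c for c in NORMS_FIELDS if c in df.columns]
    if "word" not in keep:
        raise ValueError("norms table must provide a 'word' column (map it if named differently)")
    out = df[keep].copy()
    out["word"] = out["word"].astype(str).str.strip().str.lower()
    return out


def write_tabular_norms(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_phonological_lexicon(
    path,
    strip_markers: Iterable[str] = (),
    strict: bool = True,
) -> dict[str, tuple]:
    """Read word<TAB>transcription lines into word -> phoneme tuple.

    ``strip_markers`` are stress/syllable marker characters removed before
    splitting into one-character phonemes. A duplicate word with a conflicting
    transcription is an error in strict mode; in lenient mode the first
    transcription wins and a warning is logged.
    """
    markers = set(strip_markers)
    out: dict[str, tuple] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                word, trans = line.split("\t")
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: expected exactly one TAB, got {line!r}"
                ) from None
            word = word.strip().lower()
            phonemes = tuple(ch for ch in trans if ch not in markers)
            if word in out:
                if out[word] != phonemes:
                    if strict:
                        raise ValueError(
                            f"{path}:{lineno}: conflicting transcription for "
                            f"{word!r}: {''.join(out[word])!r} vs {''.join(phonemes)!r}"
                        )
                    logger.warning(
                        "keeping first transcription for duplicate word %r", word
                    )
                continue
            out[word] = phonemes
    return out


def write_phonological_lexicon(lexicon: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word, phonemes in lexicon.items():
            fh.write(f"{word}\t{''.join(phonemes)}\n")


def read_semantic_vectors(path) -> SemanticSpace:
    """Read the embedding text format into a :class:`SemanticSpace`.

    First line: ``<vocab> <dim>``. Then one word plus ``dim`` reals per line.
    Vocabulary order is preserved. Count mismatches, duplicate words, NaNs
    and zero-norm vectors are all hard failures (checked by SemanticSpace).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"malformed embedding header: expected '<vocab> <dim>'")
        n, dim = int(header[0]), int(header[1])
        words: list[str] = []
        rows = np.empty((n, dim))
        count = 0
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"line {count + 2}: expected 1 word + {dim} values, "
                    f"got {len(parts)} fields"
                )
            if count >= n:
                count += 1
                break
            words.append(parts[0])
            rows[count] = [float(x) for x in parts[1:]]
            count += 1
    if count != n:
        raise ValueError(
            f"header declares {n} vectors but the file contains {count}"
        )
    return SemanticSpace(words, rows)


def write_semantic_vectors(space: SemanticSpace, path, fmt: str = "%.6f") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for word, row in zip(space.vocabulary, space.vectors):
            fh.write(word + " " + " ".join(fmt % x for x in row) + "\n")


def _as_norms_sources(
    norms: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
) -> dict[str, pd.DataFrame]:
    if isinstance(norms, pd.DataFrame):
        return {"norms": norms}
    return dict(norms)


def assemble_study_lexicon(
    norms: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
    lexicon: Sequence[LexEntry],
    space: SemanticSpace,
    require_iconicity: bool = False,
) -> tuple[pd.DataFrame, list[LexEntry]]:
    """Join norms, frequency lexicon and vectors under the inclusion rules.

    - Per word form, AoA is reduced to the minimum over senses (the earliest
      age), before any joining.
    - Study rows are words present in every required resource: all norms
      fields except iconicity (unless ``require_iconicity``), the frequency
      lexicon (which carries the phonology) and the semantic space.
    - The reference lexicon is every frequency-lexicon entry whose word
      appears in at least one norms source and has a semantic vector.

    Returns ``(study_table, reference_lexicon)``. The study word set is
    always a subset of the reference-lexicon word set.
    """
    sources = _as_norms_sources(norms)
    if not sources:
        raise ValueError("at least one norms source is required")

    frames = []
    norm_words: set[str] = set()
    for name, df in sorted(sources.items()):
        df = df.copy()
        df["word"] = df["word"].astype(str).str.strip().str.lower()
        norm_words.update(df["word"])
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True, sort=False)

    # earliest age across senses/sources; other fields: first non-missing
    agg = {c: "first" for c in merged.columns if c != "word"}
    if "aoa" in merged.columns:
        agg["aoa"] = "min"
    merged = (
        merged.sort_values("word", kind="stable")
        .groupby("word", as_index=False, sort=True)
        .agg(agg)
    )

    entry_by_word: dict[str, LexEntry] = {}
    for e in lexicon:
        entry_by_word.setdefault(e.word, e)

    reference = [
        e
        for w, e in sorted(entry_by_word.items())
        if w in norm_words and w in space
    ]

    required = ["aoa", "concreteness", "valence", "morph_complex"]
    if require_iconicity:
        required.append("iconicity")
    missing_cols = [c for c in required if c not in merged.columns]
    if missing_cols:
        raise ValueError(
            f"norms sources lack required columns {missing_cols}; "
            "check the column_map passed to read_tabular_norms"
        )

    ref_words = {e.word for e in reference}
    rows = merged[merged["word"].isin(ref_words)].copy()
    rows = rows.dropna(subset=required)
    if rows.empty:
        raise ValueError(
            "no word survives the resource intersection; check the "
            "column_map and the phonological-marker settings"
        )
    rows["phonemes"] = [entry_by_word[w].phoneme_string for w in rows["word"]]
    rows["frequency"] = [entry_by_word[w].frequency for w in rows["word"]]
    rows["length_phonemes"] = [len(entry_by_word[w].phonemes) for w in rows["word"]]
    if "iconicity" not in rows.columns:
        rows["iconicity"] = np.nan

    study = rows[[c for c in STUDY_COLUMNS if c in rows.columns]].reset_index(drop=True)
    return study, reference


def write_study_table(study: pd.DataFrame, path) -> None:
    """Export a study table as CSV in the fixed documented column order."""
    ordered = [c for c in STUDY_COLUMNS if c in study.columns]
    ordered += [c for c in study.columns if c not in ordered]
    study[ordered].to_csv(path, index=False)
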