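# lexsys

Word-level form–meaning systematicity measures and an age-of-acquisition
(AoA) inference pipeline, with a synthetic-lexicon generator so the whole
analysis is runnable and testable without any external resources.

The package computes **form-to-semantics consistency (FSC)** scores: the
weighted mean cosine similarity between a target word's semantic vector and
the vectors of its form-based nearest neighbours. Two neighbour-retrieval
schemes are provided:

- **te** (target-embedding): neighbours are lexicon words whose form strictly
  contains the target's form, weighted by corpus frequency (with a seeded
  random-20 fallback when nothing embeds the target);
- **ld** (edit-distance): all words within the distance of the 5th-nearest
  form (tie-inclusive), weighted by inverse Levenshtein distance.

Both run over phonological or orthographic encodings. Around them sit
readers/writers for the standard resources (norms CSV/TSV, word⟶phoneme
lexicons, embedding text format), Coltheart's-N phonological neighbourhood
density, semantic neighbourhood distance (mean cosine distance of the 20
nearest semantic neighbours), and the statistical pipeline: Box-Cox +
z-standardisation, nested OLS model ladders compared by ΔAIC, simple slopes,
random-forest regression with out-of-sample permutation importance, PCA
disentanglement and correlation reports. Robustness machinery includes a
scrambled form–meaning permutation baseline and reference-lexicon
subsampling.

## Layout

| module | contents |
| --- | --- |
| `lexsys.synthetic_lexicon` | seeded toy-lexicon generator (Zipf frequencies, bigram-projected semantic vectors with a systematicity dial, covariates, linear-model AoA) |
| `lexsys.lexicon_io` | norms / phonological-lexicon / embedding readers and writers, study-table assembly |
| `lexsys.form_space` | Levenshtein distance (scalar + vectorised one-vs-many), embedding and tie-inclusive k-th-distance neighbour retrieval, Coltheart's N |
| `lexsys.semantic_space` | cosine similarity, deterministic nearest neighbours, SND |
| `lexsys.fsc_measures` | FSC scores (te/ld, both normalisations), batch scoring, permutation baseline, subsampling |
| `lexsys.aoa_inference` | Box-Cox/z transforms, OLS + ΔAIC ladder, simple slopes, random forest, PCA, correlations |

## CLI

```bash
lexsys generate --vocab-size 1000 --systematicity 0.7 --seed 1 --out-dir data/
lexsys assemble --norms data/norms.csv --phonology data/phonology.tsv \
    --vectors data/vectors.txt --frequencies data/frequencies.csv --out study.csv
lexsys snd --vectors data/vectors.txt --out snd.csv
lexsys neighbors --phonology data/phonology.tsv --k 5 --out neighbors.tsv
lexsys fsc --study study.csv --phonology data/phonology.tsv \
    --vectors data/vectors.txt --frequencies data/frequencies.csv \
    --method ld --out scored.csv
lexsys analyze --study full.csv --out bundle.json
lexsys permute-baseline ... / lexsys subsample ...   # robustness checks
```

Every command that involves randomness takes `--seed`.

## Notes

- Scores always exclude the target from its own neighbour set; homophones
  (distance 0) are excluded from edit-distance neighbourhoods so inverse
  distance weights stay defined.
- The edit-distance score's normaliser is selectable (`literal` divides by
  the neighbour count, `weight_sum` by the summed weights); each score
  records which was used.
- ΔAIC is reported as `AIC(base) − AIC(augmented)`: positive means the added
  predictor improves fit. Only differences are meaningful; the convention is
  invariance-tested.
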