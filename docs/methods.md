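# Methods

## Problem and pipeline

The package screens for Alzheimer's-type cognitive impairment from
transcribed cookie-theft picture descriptions. The pipeline is
read → clean → extract → score relevance → classify:

1. **CHAT reading** (`chat_io`). Only the participant's main tiers
   (`*PAR:`) are speech; investigator turns and dependent annotation
   tiers (`%mor:` …) are discarded. Cleaning strips the CHAT symbology —
   square-bracketed codes, `&`-prefixed fillers and events, pause marks
   `(.)`, `@` word-form suffixes, punctuation — keeps retraced word
   material (repetitions are a signal, not noise), and lowercases.
   Each main tier is one "utterance"; the package treats utterances as
   the sentence unit throughout. Demographics come from `@ID` headers
   (standard field order: age in field 4, group in 6, education in 9,
   `MMSE=n` accepted in the custom field) or from a side-car CSV.
2. **Feature extraction** (`lexical`, `syntactic`, `semantic`,
   `features`): the 17 features listed in the README, assembled in a
   fixed canonical order with no imputation — missing age or education is
   an error, because silent demographic imputation would leak into the
   classifier.
3. **Relevance** (`relevance`) and **classification** (`classify`), below.

## Lexical error model

Both lexical error counts are defined against a dictionary, per token
occurrence, with a fixed precedence so a token is counted at most once:

- *vowel repetition*: the token is out-of-dictionary, and collapsing some
  elongated vowel run restores a dictionary word. Each maximal run of a
  single repeated vowel (length > 1) is tried at lengths 2 and 1, over
  all combinations of runs ("cooookie" → "cookie").
- *truncation*: otherwise, the token is an out-of-dictionary proper
  prefix, length ≥ 3, of some dictionary word ("fal" → "falling"). The
  length floor avoids crediting every 1–2 letter fragment.
- anything else is residual out-of-vocabulary material: logged at DEBUG,
  not a feature.

The bundled dictionary is a compact (~1,000-form) curated English
lexicon — closed-class words, inflected common verbs/nouns/adjectives,
and the complete picture vocabulary — generated by an inflection script
and swappable for any one-word-per-line file via `ResourcePaths`. A
larger lexicon sharpens the truncation test on real speech (fewer
residual OOVs); for the bundled synthetic corpus, whose vocabulary is a
subset of the lexicon, coverage is exact by construction.

## Grammar checking

Grammar errors are counted behind a one-method contract
(`check(sentence) -> findings`) so a web-service checker can be plugged
in. The shipped backend is a deterministic JSON rule set with three
regex rules over the cleaned utterance: third-person-singular pronoun
followed by a base-form verb ("he go"), immediately duplicated article
("the the"), and copula directly before a bare singular count noun ("is
boy"). Findings are raw counts, not deduplicated by span. Repetition is
counted within one utterance as token surplus: each non-stopword type
occurring k ≥ 2 times adds k − 1. The default stopword set
{a, an, the, and, is, are, to, of, in, on} excludes words that repeat
naturally in fluent speech; it is configurable, including empty.

## Semantic features

Sentence embeddings enter through a two-member contract
(`embed(text) -> vector`, `dimension`). The shipped backend hashes each
token (MD5, stable across processes and platforms) into one of 256
buckets and returns bucket counts; cosine similarity between such
vectors is a token-overlap measure. It exists so the pipeline is
deterministic and network-free; a pretrained Siamese-transformer sentence
encoder is a drop-in replacement and is what one would use for real
clinical inference. Per idea unit, the score is the **maximum** cosine
over utterances — the task is a semantic search for that idea among
short sentences, and a mean would dilute a clearly-expressed idea with
unrelated utterances. The reference ("ground truth") description
defaults to the seven idea units joined into one paragraph, overridable;
keyword matching is exact-form and case-insensitive because the keyword
list itself enumerates the inflectional variants it wants ("cookie" and
"cookies" are separate entries).

## Relevance scoring

Mutual information uses the plug-in histogram estimator on quantile bins
(default 10; variables with ≤ 10 distinct values pass through unbinned),
reported in bits and normalized by √(H(X)H(Y)) into [0, 1]. Quantile
binning makes the score invariant under strictly monotone transforms.
Constant variables have zero entropy; their normalized MI is defined as 0
with a warning. The plug-in estimator has a small positive bias on
independent data (≈ 0.01–0.02 at n = 10,000 with 10×10 bins), which the
tests bound rather than correct. Spearman's ρ is the Pearson correlation
of mid-ranks; the p-value uses the t approximation
t = ρ√((n−2)/(1−ρ²)), and power the Fisher z normal approximation at the
observed ρ (two-sided, default α = 0.05). With AD coded 1, an
informative MMSE yields a strongly negative ρ with power ≈ 1.

## Classification protocol

Stratified 10-fold cross-validation repeated 10 times (seeded); metrics
are averaged over all 100 fold results, which pools the repeat-level and
fold-level variation into one mean ± sd. Features are z-scored on the
training fold only for the distance/kernel/network models (KNN, all
SVMs, MLP); the random forest sees raw features, being scale-invariant.
The held-out fold never contributes to the scaling statistics.
Numerical choices worth stating:

- the degree-2 polynomial SVM uses the inhomogeneous kernel
  (γ⟨x,y⟩ + 1)²: with coef0 = 0 the kernel is blind to sign, and after
  centering (z-scoring) a linearly separable cohort becomes nearly
  inseparable to it;
- the "precomputed" SVM uses a precomputed **linear** Gram matrix — the
  only kernel choice that introduces no additional hyperparameter; the
  tests verify it reproduces the linear SVM fold-for-fold;
- the MLP (17→16 ReLU→8 ReLU→1 logistic, adam, ≤200 epochs, early
  stopping, seeded) is registered but excluded from default model lists:
  it is an order of magnitude slower than the rest and needs larger
  cohorts to be stable;
- precision/recall/F1 take AD as the positive class; degenerate
  denominators yield 0 with a warning rather than NaN.

## Synthetic corpus: what it does and does not emulate

The generator produces the *feature-level contrasts* the method relies
on, not realistic discourse. Each subject verbalizes each of the seven
idea units with probability `idea_coverage_prob` (rendered by one of ≥3
paraphrase templates over the picture vocabulary), adds 1–5 filler
utterances sampled without replacement from a neutral lexicon, and
appends Poisson-distributed extra keywords. Speech is then corrupted in
a fixed order — truncate (per token), elongate a vowel (per token),
inject a grammar error (per utterance, by appending a
pronoun-plus-base-verb phrase the bundled rule set detects), duplicate a
non-stopword token (per utterance) — so the expected feature counts are
simple binomial/Poisson functions of the configured rates. Demographics
and MMSE are group-coupled: MMSE = round(N(mean, sd)) clipped to [0, 30],
defaults HC 29 ± 1 and AD 20 ± 4, ages HC 46–81 / AD 49–90, education
HC 8–21 / AD 6–20, matching the demographic ranges reported for the
reference clinical cohort this corpus stands in for.

The `separable` preset (HC: coverage 0.9, corruption ≤ 0.02; AD:
coverage 0.3, truncation 0.15, elongation 0.05, grammar 0.2,
repeat 0.15) is intentionally strongly separated: it exists to verify
that the pipeline *recovers* planted structure, and classifiers reach
≈ 99% accuracy on it — far above what heterogeneous clinical speech
yields. Passing on this preset demonstrates correctness of the
machinery, not clinical performance. One consequence is a ceiling
effect: the lexical+syntactic block alone already saturates accuracy at
these corruption rates, so the *incremental* classification value of the
semantic block is not measurable on this preset (it is visible in the
relevance scores instead, where the keyword count carries far more label
information than a noise control). The `clean` preset (all corruption 0,
coverage 1, `canonical_ideas_only=True`) is the null case: every
disfluency counter must read exactly 0 and every idea similarity exactly
1 under the bundled backend. Verbatim idea rendering is what makes that
exactness possible — paraphrase templates are deliberately *not*
bag-of-words-equivalent to their idea, so the embedding path is
exercised beyond identity matches everywhere else.

Not modeled: topic drift, investigator interleaving, hesitation
phenomena beyond the coded fillers, coarticulation/phonology, dialect,
and any correlation structure between corruption types within a subject
beyond what the shared rates induce.

## Problem sizes and determinism

Default study sizes: 200 subjects (100/100) for pipeline-level checks
and the acceptance script, 10×10-fold evaluation, 20 seeded replicate
cohorts for the relevance-recovery check. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; corpus
generation, fold assignment and model fitting are reproducible
bit-for-bit given the seed, and generated `.cha` files round-trip through
the reader to identical token sequences.

## Known limitations

- The truncation/elongation classifiers are heuristics; tokens like
  dialect forms or proper names land in residual OOV and are silently
  ignored (logged at DEBUG).
- The bundled grammar rules cover three error families only; counts from
  a full checker service are not comparable in magnitude.
- Hashed bag-of-words cosine captures lexical overlap, not meaning: a
  perfect paraphrase with disjoint vocabulary scores near 0. Conclusions
  about semantic-feature usefulness on real data require a real sentence
  encoder.
- The plug-in NMI estimator is biased upward at small n; compare features
  against a noise control at the same n, as the relevance report does.
- CHAT support is the dialect subset described above, not the full spec;
  unrecognized bracket codes are stripped wholesale.
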