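"""Assembly of the 17-feature vector and the on-disk feature table.

Canonical feature order (2 demographic + 4 lexical + 2 syntactic +
9 semantic = 17):

    age, education,
    truncation_count, vowel_repetition_count, vocabulary_length,
    lexical_diversity,
    grammar_error_count, repeated_word_count,
    keyword_count, idea_similarity_1 .. idea_similarity_7,
    ground_truth_similarity

Gender is metadata, not a feature; MMSE is a relevance target only and is
carried alongside the table, never inside the vector.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chat_io import Transcript, to_plain_text
from .errors import MissingDemographicsError
from .lexical import lexical_profile
from .resources import ResourcePaths, load_dictionary, load_stopwords
from .semantic import (
    EmbeddingBackend,
    HashedBowBackend,
    KeywordList,
    MainIdeas,
    semantic_profile,
)
from .syntactic import BundledRuleChecker, GrammarChecker, syntactic_profile

N_IDEAS = 7

FEATURE_NAMES: tuple[str, ...] = (
    "age",
    "education",
    "truncation_count",
    "vowel_repetition_count",
    "vocabulary_length",
    "lexical_diversity",
    "grammar_error_count",
    "repeated_word_count",
    "keyword_count",
    *[f"idea_similarity_{i}" for i in range(1, N_IDEAS + 1)],
    "ground_truth_similarity",
)

#: the lexical+syntactic-only ablation subset
LEXSYN_FEATURES: tuple[str, ...] = FEATURE_NAMES[2:8]


@dataclass
class FeatureExtractor:
    """Caches the configured resources once and extracts per transcript."""

    paths: ResourcePaths | None = None
    backend: EmbeddingBackend | None = None
    checker: GrammarChecker | None = None

    def __post_init__(self) -> None:
        paths = self.paths or ResourcePaths()
        self.dictionary = load_dictionary(paths.dictionary)
        self.stopwords = load_stopwords(paths.stopwords)
        self.keywords = KeywordList.bundled(paths)
        self.ideas = MainIdeas.bundled(paths)
        self.backend = self.backend or HashedBowBackend()
        self.checker = self.checker or BundledRuleChecker(paths.grammar_rules)

    def extract(self, transcript: Transcript) -> np.ndarray:
        return build_feature_vector(
            transcript,
            dictionary=self.dictionary,
            stopwords=self.stopwords,
            keywords=self.keywords,
            ideas=self.ideas,
            backend=self.backend,
            checker=self.checker,
        )


def build_feature_vector(
    transcript: Transcript,
    dictionary: frozenset[str],
    stopwords: frozenset[str],
    keywords: KeywordList,
    ideas: MainIdeas,
    backend: EmbeddingBackend,
    checker: GrammarChecker,
) -> np.ndarray:
    """Run every extraction stage and return the 17 features in order."""
    if transcript.age is None or transcript.education is None:
        raise MissingDemographicsError(
            f"{transcript.subject_id}: age and education are required"
        )
    plain = to_plain_text(transcript)  # raises on empty transcripts
    lex = lexical_profile(list(plain.tokens), dictionary)
    syn = syntactic_profile(transcript.utterances, checker, stopwords)
    sem = semantic_profile(
        transcript.utterances, plain.tokens, plain.text, keywords, ideas, backend
    )
    if len(sem.idea_similarities) != N_IDEAS:
        raise ValueError(
            f"expected {N_IDEAS} idea similarities, got {len(sem.idea_similarities)}"
        )
    vector = np.array(
        [
            float(transcript.age),
            float(transcript.education),
            float(lex.truncation_count),
            float(lex.vowel_repetition_count),
            float(lex.vocabulary_length),
            float(lex.lexical_diversity),
            float(syn.grammar_error_count),
            float(syn.repeated_word_count),
            float(sem.keyword_count),
            *[float(s) for s in sem.idea_similarities],
            float(sem.ground_truth_similarity),
        ]
    )
    assert vector.shape == (len(FEATURE_NAMES),)
    return vector


def write_feature_table(
    vectors: list[np.ndarray],
    labels: list[str],
    path: str | Path,
    subject_ids: list[str] | None = None,
    mmse: list[int | None] | None = None,
) -> pd.DataFrame:
    """Write the per-subject feature table as CSV and return it."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels differ in length")
    subject_ids = subject_ids or [f"s{i:04d}" for i in range(len(vectors))]
    frame = pd.DataFrame(
        np.array(vectors).reshape(len(vectors), len(FEATURE_NAMES)),
        columns=list(FEATURE_NAMES),
    )
    frame.insert(0, "subject_id", subject_ids)
    frame["label"] = labels
    if mmse is not None:
        frame["mmse"] = [m if m is not None else np.nan for m in mmse]
    frame.to_csv(path, index=False, float_format="%.15g")
    return frame


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, enforcing the canonical column schema."""
    frame = pd.read_csv(path)
    expected = ["subject_id", *FEATURE_NAMES, "label"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return frame


def transcripts_to_table(
    transcripts: list[Transcript],
    extractor: FeatureExtractor | None = None,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[tuple[str, Exception]]]:
    """Extract every transcript; optionally isolate per-subject failures.

    Returns the table (without file I/O) and the list of failures when
    ``on_error="skip"``.
    """
    extractor = extractor or FeatureExtractor()
    rows, sids, labels, mmses = [], [], [], []
    failures: list[tuple[str, Exception]] = []
    for tr in transcripts:
        try:
            rows.append(extractor.extract(tr))
        except Exception as exc:
            if on_error == "skip":
                failures.append((tr.subject_id, exc))
                continue
            raise
        sids.append(tr.subject_id)
        labels.append(tr.label)
        mmses.append(tr.mmse)
    frame = pd.DataFrame(
        np.array(rows).reshape(len(rows), len(FEATURE_NAMES)),
        columns=list(FEATURE_NAMES),
    )
    frame.insert(0, "subject_id", sids)
    frame["label"] = labels
    frame["mmse"] = [m if m is not None else np.nan for m in mmses]
    return frame, failures
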