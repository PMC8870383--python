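"""Semantic features: keyword counts and sentence-embedding cosine similarity.

A description is scored three ways: (1) how many picture content words
(keyword list) it uses; (2) how close each of the seven expected idea
units comes to some utterance, measured as the maximum cosine similarity
between sentence embeddings — a semantic search of the description, one
short sentence at a time; (3) the overall cosine similarity of the whole
description to a reference ("ground truth") description.

Embeddings come from a pluggable backend.  The shipped backend is a
deterministic feature-hashed bag of words (256 dimensions, MD5-keyed), so
the whole pipeline runs offline and reproducibly; any SBERT-style sentence
encoder with an ``embed``/``dimension`` surface is a drop-in replacement.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

from .chat_io import Utterance
from .errors import DimensionMismatchError, EmptyTranscriptError, ZeroVectorError
from .resources import ResourcePaths, load_ground_truth, load_ideas, load_keywords


class EmbeddingBackend(Protocol):
    dimension: int

    def embed(self, sentence: str) -> np.ndarray: ...


class HashedBowBackend:
    """Feature-hashed bag-of-words sentence embedder.

    Each whitespace token is hashed (MD5 of the token bytes, stable across
    processes) into one of `dimension` buckets; the embedding is the bucket
    count vector.  Deterministic, training-free, and cosine between two
    embeddings approximates token-overlap similarity.
    """

    def __init__(self, dimension: int = 256) -> None:
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = dimension

    def _bucket(self, token: str) -> int:
        digest = hashlib.md5(token.encode("utf-8")).digest()
        return int.from_bytes(digest[:8], "big") % self.dimension

    def embed(self, sentence: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in sentence.lower().split():
            vec[self._bucket(token)] += 1.0
        return vec


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u.v / (|u||v|); raises on zero vectors or shape mismatch."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"shapes {u.shape} and {v.shape} differ")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class MainIdeas:
    """The expected idea units of the picture plus a reference description."""

    ideas: tuple[str, ...]
    ground_truth: str

    @classmethod
    def bundled(cls, paths: ResourcePaths | None = None) -> "MainIdeas":
        paths = paths or ResourcePaths()
        return cls(
            ideas=tuple(load_ideas(paths.ideas)),
            ground_truth=load_ground_truth(paths.ground_truth),
        )


@dataclass(frozen=True)
class KeywordList:
    words: tuple[str, ...]

    @classmethod
    def bundled(cls, paths: ResourcePaths | None = None) -> "KeywordList":
        paths = paths or ResourcePaths()
        return cls(words=tuple(load_keywords(paths.keywords)))


@dataclass(frozen=True)
class SemanticProfile:
    keyword_count: int
    idea_similarities: tuple[float, ...]
    ground_truth_similarity: float


def count_keywords(tokens: Sequence[str], keywords: KeywordList) -> int:
    """Occurrences of exact keyword forms (case-insensitive, no stemming)."""
    vocab = set(keywords.words)
    return sum(1 for t in tokens if t.lower() in vocab)


def idea_similarities(
    utterances: Iterable[Utterance],
    ideas: MainIdeas,
    backend: EmbeddingBackend,
) -> list[float]:
    """Per idea, the best cosine match over the description's utterances."""
    utt_vecs = [backend.embed(" ".join(u.tokens)) for u in utterances if u.tokens]
    if not utt_vecs:
        raise EmptyTranscriptError("no utterances to embed")
    sims = []
    for idea in ideas.ideas:
        idea_vec = backend.embed(idea)
        sims.append(max(cosine_similarity(u, idea_vec) for u in utt_vecs))
    return sims


def ground_truth_similarity(
    text: str, ideas: MainIdeas, backend: EmbeddingBackend
) -> float:
    """Cosine similarity of the whole description to the reference text."""
    if not text.strip():
        raise EmptyTranscriptError("empty description text")
    return cosine_similarity(backend.embed(text), backend.embed(ideas.ground_truth))


def semantic_profile(
    utterances: list[Utterance],
    tokens: Sequence[str],
    text: str,
    keywords: KeywordList,
    ideas: MainIdeas,
    backend: EmbeddingBackend,
) -> SemanticProfile:
    return SemanticProfile(
        keyword_count=count_keywords(tokens, keywords),
        idea_similarities=tuple(idea_similarities(utterances, ideas, backend)),
        ground_truth_similarity=ground_truth_similarity(text, ideas, backend),
    )
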