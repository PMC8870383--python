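"""Grammatical-error and word-repetition counts per utterance.

Grammar checking sits behind a small contract so the backend can be a
network service or the bundled deterministic rule set.  The bundled
checker ships as editable JSON data: each rule is a regular expression
over the cleaned, space-joined utterance, covering subject-verb
agreement with third-person pronouns, duplicated articles, and missing
determiners before bare singular count nouns.

Word repetition is counted within one utterance ("sentence"): each
non-stopword type occurring k >= 2 times contributes k - 1.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

from .chat_io import Utterance
from .errors import BackendUnavailableError
from .resources import ResourcePaths, load_grammar_rules

#: default exclusions for repetition counting: words that repeat naturally
DEFAULT_STOPWORDS = frozenset(
    {"a", "an", "the", "and", "is", "are", "to", "of", "in", "on"}
)


@dataclass(frozen=True)
class Finding:
    rule_id: str
    span: tuple[int, int]


class GrammarChecker(Protocol):
    def check(self, sentence: str) -> list[Finding]: ...


class BundledRuleChecker:
    """Deterministic regex rule set loaded from JSON data."""

    def __init__(self, rules_path: str | Path | None = None) -> None:
        path = Path(rules_path) if rules_path else ResourcePaths().grammar_rules
        self.rules = [
            (rule["id"], re.compile(rule["pattern"]))
            for rule in load_grammar_rules(path)
        ]

    def check(self, sentence: str) -> list[Finding]:
        findings = []
        for rule_id, pattern in self.rules:
            for m in pattern.finditer(sentence):
                findings.append(Finding(rule_id, m.span()))
        return findings


@dataclass(frozen=True)
class SyntacticProfile:
    grammar_error_count: int
    repeated_word_count: int


def count_grammar_errors(
    utterances: Iterable[Utterance], checker: GrammarChecker
) -> int:
    """Sum of checker findings over utterances; raw counts, no dedup."""
    total = 0
    for utt in utterances:
        sentence = " ".join(utt.tokens)
        try:
            findings = checker.check(sentence)
        except (OSError, ConnectionError) as exc:  # pragma: no cover - network path
            raise BackendUnavailableError(f"grammar backend failed: {exc}") from exc
        total += len(findings)
    return total


def count_repeated_words(
    utterances: Iterable[Utterance],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> int:
    """Token-surplus repetitions within each utterance, stopwords excluded."""
    total = 0
    for utt in utterances:
        counts = Counter(t for t in utt.tokens if t not in stopwords)
        total += sum(k - 1 for k in counts.values() if k >= 2)
    return total


def syntactic_profile(
    utterances: list[Utterance],
    checker: GrammarChecker,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> SyntacticProfile:
    return SyntacticProfile(
        grammar_error_count=count_grammar_errors(utterances, checker),
        repeated_word_count=count_repeated_words(utterances, stopwords),
    )
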