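"""Lexical metrics: truncation, vowel repetition, vocabulary length, diversity.

All four metrics are bag-of-words statistics of a cleaned token list.
Out-of-dictionary tokens are classified, in order of precedence, as vowel
repetitions (an elongated vowel run collapses back to a dictionary word,
the bardilalia marker), then as truncations (a proper prefix, length >= 3,
of some dictionary word — an unfinished word), and otherwise logged as
residual out-of-vocabulary material.  Lexical diversity is the ratio of
text length to vocabulary length, LD = TL / VL; LD = 1 means every token
is distinct, larger values mean a more repetitive vocabulary.
"""
from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass

from .errors import UndefinedDiversityError

log = logging.getLogger(__name__)

_VOWEL_RUN = re.compile(r"([aeiou])\1+")

MIN_PREFIX_LEN = 3


@dataclass(frozen=True)
class LexicalProfile:
    truncation_count: int
    vowel_repetition_count: int
    text_length: int
    vocabulary_length: int
    lexical_diversity: float


def is_vowel_repetition(token: str, dictionary: frozenset[str]) -> bool:
    """True if collapsing some elongated vowel run makes `token` a word.

    Each maximal run of one repeated vowel with length > 1 is tried reduced
    to length 2 and length 1, over all combinations of runs.  The token
    itself must be out-of-dictionary.
    """
    if token in dictionary:
        return False
    runs = list(_VOWEL_RUN.finditer(token))
    if not runs:
        return False
    options = []
    for m in runs:
        vowel = m.group(1)
        lengths = {min(len(m.group()), 2), 1}
        options.append(sorted(vowel * n for n in lengths))
    for combo in itertools.product(*options):
        parts = []
        last = 0
        for m, repl in zip(runs, combo):
            parts.append(token[last : m.start()])
            parts.append(repl)
            last = m.end()
        parts.append(token[last:])
        candidate = "".join(parts)
        if candidate != token and candidate in dictionary:
            return True
    return False


def is_truncation(token: str, dictionary: frozenset[str]) -> bool:
    """True if `token` is OOV and a proper prefix (len >= 3) of a word."""
    if token in dictionary or len(token) < MIN_PREFIX_LEN:
        return False
    return any(w.startswith(token) and w != token for w in dictionary)


def count_vowel_repetitions(tokens: list[str], dictionary: frozenset[str]) -> int:
    if not dictionary:
        raise ValueError("dictionary must be non-empty")
    return sum(1 for t in tokens if is_vowel_repetition(t, dictionary))


def count_truncations(tokens: list[str], dictionary: frozenset[str]) -> int:
    """Count unfinished-word tokens (per occurrence).

    Vowel-repetition classification takes precedence: a token counts at
    most once across the two lexical error categories.
    """
    if not dictionary:
        raise ValueError("dictionary must be non-empty")
    count = 0
    for t in tokens:
        if t in dictionary or is_vowel_repetition(t, dictionary):
            continue
        if is_truncation(t, dictionary):
            count += 1
        else:
            log.debug("residual OOV token (neither truncation nor elongation): %r", t)
    return count


def vocabulary_metrics(tokens: list[str]) -> tuple[int, int]:
    """Return (TL, VL): token count and distinct-token count."""
    return len(tokens), len(set(tokens))


def lexical_diversity(tl: int, vl: int) -> float:
    """LD = TL / VL (inverse type-token ratio)."""
    if vl == 0:
        raise UndefinedDiversityError("vocabulary length is zero")
    return tl / vl


def lexical_profile(tokens: list[str], dictionary: frozenset[str]) -> LexicalProfile:
    tl, vl = vocabulary_metrics(tokens)
    return LexicalProfile(
        truncation_count=count_truncations(tokens, dictionary),
        vowel_repetition_count=count_vowel_repetitions(tokens, dictionary),
        text_length=tl,
        vocabulary_length=vl,
        lexical_diversity=lexical_diversity(tl, vl),
    )
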