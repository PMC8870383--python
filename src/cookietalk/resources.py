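"""Loaders for the bundled resource files.

Every resource (dictionary, keyword list, main ideas, ground-truth
description, grammar rules, stopwords) ships as plain text/JSON inside the
package and can be swapped for an external file via :class:`ResourcePaths`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path


def _bundled(name: str) -> Path:
    return Path(str(importlib_resources.files("cookietalk").joinpath("data", name)))


@dataclass(frozen=True)
class ResourcePaths:
    """File locations for all swappable resources (defaults: bundled data)."""

    dictionary: Path = field(default_factory=lambda: _bundled("dictionary.txt"))
    keywords: Path = field(default_factory=lambda: _bundled("keywords.txt"))
    ideas: Path = field(default_factory=lambda: _bundled("ideas.txt"))
    ground_truth: Path = field(default_factory=lambda: _bundled("ground_truth.txt"))
    grammar_rules: Path = field(default_factory=lambda: _bundled("grammar_rules.json"))
    stopwords: Path = field(default_factory=lambda: _bundled("stopwords.txt"))
    templates: Path = field(default_factory=lambda: _bundled("templates.json"))
    filler_lexicon: Path = field(default_factory=lambda: _bundled("filler_lexicon.txt"))


def load_wordlist(path: Path) -> list[str]:
    """Read a one-word-per-line UTF-8 file, ignoring blanks."""
    return [w for w in path.read_text(encoding="utf-8").split("\n") if w.strip()]


def load_dictionary(path: Path) -> frozenset[str]:
    words = load_wordlist(path)
    if not words:
        raise ValueError(f"dictionary file {path} is empty")
    bad = [w for w in words if w != w.lower() or any(c.isdigit() for c in w)]
    if bad:
        raise ValueError(f"dictionary entries must be lowercase words: {bad[:5]}")
    return frozenset(words)


def load_keywords(path: Path) -> list[str]:
    words = [w.lower() for w in load_wordlist(path)]
    if len(set(words)) != len(words):
        raise ValueError("keyword list contains duplicates")
    return words


def load_ideas(path: Path) -> list[str]:
    ideas = [line.lower() for line in load_wordlist(path)]
    if not ideas:
        raise ValueError("main-ideas file is empty")
    return ideas


def load_ground_truth(path: Path) -> str:
    text = path.read_text(encoding="utf-8").strip().lower()
    if not text:
        raise ValueError("ground-truth description is empty")
    return text


def load_stopwords(path: Path) -> frozenset[str]:
    return frozenset(w.lower() for w in load_wordlist(path))


def load_grammar_rules(path: Path) -> list[dict]:
    rules = json.loads(path.read_text(encoding="utf-8"))
    for rule in rules:
        if not {"id", "pattern"} <= rule.keys():
            raise ValueError(f"grammar rule missing id/pattern: {rule}")
    return rules


def load_templates(path: Path) -> dict[str, list[str]]:
    return json.loads(path.read_text(encoding="utf-8"))
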