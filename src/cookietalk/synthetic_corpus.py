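"""Synthetic cookie-theft corpus generator.

Emulates the statistical structure the pipeline assumes in HC/AD
picture-description data: each subject verbalizes a random subset of the
seven idea units (rendered by paraphrase templates over the picture
vocabulary), adds filler utterances and extra keywords, and the resulting
speech is then corrupted in a fixed order — word truncation, vowel
elongation, grammar-error injection, within-utterance word repetition —
at group-specific per-token/per-utterance rates.  Demographics and MMSE
are group-coupled (HC around 29 MMSE, AD around 20).  Everything is
reproducible from the config seed, in memory or as .cha files.

This generator models feature-level contrasts, not discourse: see
docs/methods.md for what it does and does not emulate.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chat_io import AD, HC, Transcript, Utterance, write_chat
from .resources import ResourcePaths, load_dictionary, load_keywords, load_templates, load_wordlist
from .syntactic import DEFAULT_STOPWORDS

#: tokens appended to an utterance to inject a subject-verb agreement error
_GRAMMAR_ERROR_TOKENS = ("and", "he", "go")

_VOWELS = "aeiou"


@dataclass(frozen=True)
class GroupParams:
    """Generation settings for one diagnostic group."""

    idea_coverage_prob: float
    keyword_rate: float
    truncation_prob: float
    vowel_elongation_prob: float
    grammar_error_prob: float
    repeat_prob: float
    vocab_size: int
    utterance_count: tuple[int, int]  # filler utterances, inclusive range
    age_range: tuple[int, int]
    education_range: tuple[int, int]
    mmse_mean: float
    mmse_sd: float

    def __post_init__(self) -> None:
        for name in (
            "idea_coverage_prob",
            "truncation_prob",
            "vowel_elongation_prob",
            "grammar_error_prob",
            "repeat_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.keyword_rate < 0:
            raise ValueError("keyword_rate must be >= 0")
        if self.vocab_size < 8:
            raise ValueError("vocab_size too small to form filler utterances")
        for name in ("utterance_count", "age_range", "education_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is degenerate: ({lo}, {hi})")
        if self.mmse_sd < 0:
            raise ValueError("mmse_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_hc: int
    n_ad: int
    hc: GroupParams
    ad: GroupParams
    seed: int = 0
    canonical_ideas_only: bool = False
    paths: ResourcePaths = field(default_factory=ResourcePaths)


def default_separable_config(n_hc: int = 100, n_ad: int = 100, seed: int = 0) -> GeneratorConfig:
    """The documented strong-separation preset.

    HC speakers cover most ideas with barely corrupted speech; AD speakers
    cover few ideas with frequent truncation, elongation, grammar errors
    and repetition; MMSE means sit at the group means of the reference
    cohort (HC 29, AD 20).
    """
    hc = GroupParams(
        idea_coverage_prob=0.9,
        keyword_rate=1.0,
        truncation_prob=0.01,
        vowel_elongation_prob=0.01,
        grammar_error_prob=0.02,
        repeat_prob=0.02,
        vocab_size=60,
        utterance_count=(2, 5),
        age_range=(46, 81),
        education_range=(8, 21),
        mmse_mean=29.0,
        mmse_sd=1.0,
    )
    ad = GroupParams(
        idea_coverage_prob=0.3,
        keyword_rate=0.3,
        truncation_prob=0.15,
        vowel_elongation_prob=0.05,
        grammar_error_prob=0.2,
        repeat_prob=0.15,
        vocab_size=60,
        utterance_count=(1, 4),
        age_range=(49, 90),
        education_range=(6, 20),
        mmse_mean=20.0,
        mmse_sd=4.0,
    )
    return GeneratorConfig(n_hc=n_hc, n_ad=n_ad, hc=hc, ad=ad, seed=seed)


def clean_config(n_hc: int = 5, n_ad: int = 5, seed: int = 0) -> GeneratorConfig:
    """Corruption-free preset: full idea coverage, verbatim idea wording.

    Useful as a pipeline null case — every disfluency counter must read 0
    and every idea similarity must be exactly 1 under the bundled backend.
    """
    base = default_separable_config(n_hc, n_ad, seed)
    clean = dict(
        idea_coverage_prob=1.0,
        keyword_rate=0.0,
        truncation_prob=0.0,
        vowel_elongation_prob=0.0,
        grammar_error_prob=0.0,
        repeat_prob=0.0,
    )
    return replace(
        base,
        hc=replace(base.hc, **clean),
        ad=replace(base.ad, **clean),
        canonical_ideas_only=True,
    )


class _Corruptor:
    """Applies the four corruption passes in fixed order."""

    def __init__(self, dictionary: frozenset[str], rng: np.random.Generator):
        self.dictionary = dictionary
        self.rng = rng

    def truncate(self, token: str) -> str | None:
        """Cut the token to an out-of-dictionary proper prefix (len >= 3)."""
        for cut in range(len(token) - 1, 2, -1):
            prefix = token[:cut]
            if prefix not in self.dictionary:
                return prefix
        return None

    def elongate(self, token: str) -> str | None:
        """Stretch one vowel into a run of 3 so collapsing recovers a word."""
        positions = [i for i, c in enumerate(token) if c in _VOWELS]
        if not positions:
            return None
        i = positions[self.rng.integers(len(positions))]
        stretched = token[:i] + token[i] * 3 + token[i + 1 :]
        return stretched if stretched not in self.dictionary else None

    def corrupt_utterance(self, tokens: list[str], params: GroupParams) -> list[str]:
        out = []
        for t in tokens:
            if (
                len(t) >= 5
                and t in self.dictionary
                and self.rng.random() < params.truncation_prob
            ):
                cut = self.truncate(t)
                if cut is not None:
                    out.append(cut)
                    continue
            if (
                len(t) >= 3
                and t in self.dictionary
                and self.rng.random() < params.vowel_elongation_prob
            ):
                stretched = self.elongate(t)
                if stretched is not None:
                    out.append(stretched)
                    continue
            out.append(t)
        if self.rng.random() < params.grammar_error_prob:
            out = out + list(_GRAMMAR_ERROR_TOKENS)
        if self.rng.random() < params.repeat_prob:
            candidates = [
                i for i, t in enumerate(out)
                if t not in DEFAULT_STOPWORDS and t in self.dictionary
            ]
            if candidates:
                i = candidates[self.rng.integers(len(candidates))]
                out = out[: i + 1] + [out[i]] + out[i + 1 :]
        return out


def _make_subject(
    sid: str,
    label: str,
    params: GroupParams,
    rng: np.random.Generator,
    ideas: list[str],
    templates: dict[str, list[str]],
    keywords: list[str],
    filler: list[str],
    corruptor: _Corruptor,
    canonical_only: bool,
) -> Transcript:
    age = int(rng.integers(params.age_range[0], params.age_range[1] + 1))
    education = int(rng.integers(params.education_range[0], params.education_range[1] + 1))
    gender = "female" if rng.random() < 0.5 else "male"
    mmse = int(np.clip(round(rng.normal(params.mmse_mean, params.mmse_sd)), 0, 30))

    utterances: list[list[str]] = []
    for idea in ideas:
        if rng.random() < params.idea_coverage_prob:
            if canonical_only:
                rendered = idea
            else:
                variants = templates[idea]
                rendered = variants[rng.integers(len(variants))]
            utterances.append(rendered.split())

    lexicon = filler[: params.vocab_size]
    n_filler = int(rng.integers(params.utterance_count[0], params.utterance_count[1] + 1))
    for _ in range(n_filler):
        n_words = int(rng.integers(4, 9))
        words = list(rng.choice(lexicon, size=min(n_words, len(lexicon)), replace=False))
        n_kw = rng.poisson(params.keyword_rate)
        if n_kw > 0:
            words += list(rng.choice(keywords, size=min(n_kw, len(keywords)), replace=False))
        utterances.append(words)

    corrupted = [corruptor.corrupt_utterance(u, params) for u in utterances]
    return Transcript(
        subject_id=sid,
        utterances=[
            Utterance("PAR", " ".join(u), tuple(u)) for u in corrupted if u
        ],
        age=age,
        education=education,
        gender=gender,
        mmse=mmse,
        label=label,
    )


def generate_corpus(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> list[Transcript]:
    """Generate the labeled corpus; optionally write .cha files + CSV.

    Subjects are generated HC first then AD from a single seeded stream,
    so identical configs give identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    paths = config.paths
    ideas = [line.lower() for line in load_wordlist(paths.ideas)]
    templates = load_templates(paths.templates)
    missing = [i for i in ideas if i not in templates]
    if missing:
        raise ValueError(f"no templates for ideas: {missing}")
    keywords = load_keywords(paths.keywords)
    filler = load_wordlist(paths.filler_lexicon)
    dictionary = load_dictionary(paths.dictionary)
    for group in (config.hc, config.ad):
        if group.vocab_size > len(filler):
            raise ValueError(
                f"vocab_size={group.vocab_size} exceeds filler lexicon ({len(filler)})"
            )
    corruptor = _Corruptor(dictionary, rng)

    transcripts = []
    for label, n, params in ((HC, config.n_hc, config.hc), (AD, config.n_ad, config.ad)):
        for i in range(n):
            transcripts.append(
                _make_subject(
                    f"{label.lower()}{i:04d}",
                    label,
                    params,
                    rng,
                    ideas,
                    templates,
                    keywords,
                    filler,
                    corruptor,
                    config.canonical_ideas_only,
                )
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for tr in transcripts:
            write_chat(tr, out_dir / f"{tr.subject_id}.cha")
        with open(out_dir / "demographics.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "age", "education", "gender", "mmse", "label"])
            for tr in transcripts:
                writer.writerow(
                    [tr.subject_id, tr.age, tr.education, tr.gender, tr.mmse, tr.label]
                )
    return transcripts
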