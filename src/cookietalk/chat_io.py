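"""Reading and cleaning CHAT (.cha) picture-description transcripts.

Supports the CHAT dialect subset used by picture-description corpora:
``@``-headers (including ``@ID`` demographic lines), main speaker tiers
(``*PAR:``, ``*INV:``), dependent tiers (``%mor:`` etc., always skipped),
and the inline codes that annotate disfluent speech.  Only the
participant's own word material survives cleaning: bracketed codes,
``&``-prefixed fillers, pause marks and punctuation are stripped, retraced
words are kept, and everything is lowercased.
"""
from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

from .errors import EmptyTranscriptError

log = logging.getLogger(__name__)

HC = "HC"
AD = "AD"
UNKNOWN = "unknown"

#: characters that must never survive in a cleaned token
_FORBIDDEN = re.compile(r"[A-Z\[\]<>&@.,!?]")

_BRACKET_GROUP = re.compile(r"\[[^\]]*\]")
_AMP_TOKEN = re.compile(r"(?<!\S)&\S+")
_PAUSE = re.compile(r"\(\.{1,3}\)")
_AT_SUFFIX = re.compile(r"@\S*")
_STRIP_CHARS = re.compile(r"[<>()\[\]&@.,!?;:\"+/=^_~*‡„“”]")


@dataclass(frozen=True)
class Utterance:
    """One participant main-tier line, raw and cleaned."""

    speaker: str
    raw: str
    tokens: tuple[str, ...]


@dataclass
class Transcript:
    """One subject's parsed session: participant speech plus metadata."""

    subject_id: str
    utterances: list[Utterance]
    age: int | None = None
    education: int | None = None
    gender: str | None = None
    mmse: int | None = None
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.education is not None and self.education < 0:
            raise ValueError(f"education must be >= 0, got {self.education}")
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"MMSE must lie in [0, 30], got {self.mmse}")


@dataclass(frozen=True)
class PlainText:
    """Whitespace-normalized lowercase text with its flat token list."""

    text: str
    tokens: tuple[str, ...]


def clean_utterance(raw: str) -> list[str]:
    """Strip CHAT symbology from a main-tier string and tokenize.

    Removal rules: ``[...]`` code groups (retracing markers, error codes,
    postcodes) vanish wholesale; ``&``-prefixed fillers and events vanish;
    pause codes ``(.)``/``(..)``/``(...)`` vanish; ``@`` word-form suffixes
    are cut; angle brackets and parentheses are dropped but the words they
    wrap are kept (retraced material is speech); remaining punctuation is
    dropped and the result lowercased.  Idempotent by construction.
    """
    s = _BRACKET_GROUP.sub(" ", raw)
    s = _AMP_TOKEN.sub(" ", s)
    s = _PAUSE.sub(" ", s)
    s = _AT_SUFFIX.sub("", s)
    s = _STRIP_CHARS.sub(lambda m: "" if m.group() in "()<>" else " ", s)
    tokens = [t for t in s.lower().split() if any(c.isalpha() for c in t)]
    return [t.strip("'-") for t in tokens if t.strip("'-")]


def _parse_id_header(value: str) -> dict:
    """Parse a CHAT ``@ID`` field string.

    Standard field order: language|corpus|code|age|sex|group|SES|role|
    education|custom.  The custom slot may carry ``MMSE=<n>``.
    """
    fields = [f.strip() for f in value.split("|")]
    if len(fields) < 8:
        raise ValueError(f"@ID line has {len(fields)} fields, expected >= 8")
    meta: dict = {"code": fields[2]}
    age_match = re.match(r"(\d+)", fields[3])
    meta["age"] = int(age_match.group(1)) if age_match else None
    meta["gender"] = fields[4] or None
    group = fields[5].lower()
    if "ad" in group or "dementia" in group:
        meta["label"] = AD
    elif "control" in group or group == "hc":
        meta["label"] = HC
    else:
        meta["label"] = UNKNOWN
    meta["education"] = None
    if len(fields) > 8 and re.fullmatch(r"\d+", fields[8]):
        meta["education"] = int(fields[8])
    meta["mmse"] = None
    if len(fields) > 9:
        mmse_match = re.search(r"(?:MMSE=)?(\d+)", fields[9])
        if mmse_match:
            meta["mmse"] = int(mmse_match.group(1))
    return meta


def read_chat(
    path: str | Path,
    participant: str = "PAR",
    demographics: dict[str, dict] | None = None,
) -> Transcript:
    """Read one .cha file into a :class:`Transcript`.

    Only main tiers of `participant` become utterances; investigator tiers
    and all dependent (%) tiers are skipped.  ``@ID`` headers supply
    demographics; a side-car demographics mapping (see
    :func:`read_demographics_csv`) overrides or completes them.

    Raises
    ------
    FileNotFoundError
        If `path` does not exist.
    EmptyTranscriptError
        If no participant utterance with word material is found.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").split("\n")

    # join continuation lines (leading tab or spaces) onto their tier line
    tiers: list[str] = []
    for line in lines:
        if line[:1] in ("\t", " ") and tiers:
            tiers[-1] += " " + line.strip()
        elif line.strip():
            tiers.append(line.rstrip())

    subject_id = path.stem
    meta: dict = {}
    utterances: list[Utterance] = []
    for tier in tiers:
        if tier.startswith("@"):
            head, _, value = tier.partition(":")
            if head.strip() == "@ID":
                try:
                    parsed = _parse_id_header(value.strip())
                except ValueError as exc:
                    warnings.warn(f"{path.name}: malformed @ID header ({exc})")
                    continue
                if parsed.pop("code") == participant:
                    meta.update(parsed)
            elif head.strip() == "@PID":
                subject_id = value.strip() or subject_id
        elif tier.startswith("*"):
            speaker, _, content = tier[1:].partition(":")
            if speaker.strip() != participant:
                continue
            tokens = clean_utterance(content)
            if tokens:
                utterances.append(
                    Utterance(speaker.strip(), content.strip(), tuple(tokens))
                )
        elif tier.startswith("%"):
            continue  # dependent tiers are annotation, not speech
        else:
            log.debug("%s: ignoring unrecognized line %r", path.name, tier[:40])

    if demographics and subject_id in demographics:
        for key, value in demographics[subject_id].items():
            if value is not None:
                meta[key] = value

    if not utterances:
        raise EmptyTranscriptError(f"{path}: no participant speech found")
    return Transcript(
        subject_id=subject_id,
        utterances=utterances,
        age=meta.get("age"),
        education=meta.get("education"),
        gender=meta.get("gender"),
        mmse=meta.get("mmse"),
        label=meta.get("label", UNKNOWN),
    )


def to_plain_text(transcript: Transcript) -> PlainText:
    """Concatenate the cleaned utterances into one whitespace-normalized text."""
    if not transcript.utterances:
        raise EmptyTranscriptError(f"{transcript.subject_id}: no utterances")
    tokens: list[str] = []
    for utt in transcript.utterances:
        tokens.extend(utt.tokens)
    return PlainText(text=" ".join(tokens), tokens=tuple(tokens))


def read_demographics_csv(path: str | Path) -> dict[str, dict]:
    """Load a side-car demographics table keyed by subject_id.

    Expected columns: subject_id, age, education, gender, mmse, label.
    Missing or blank numeric cells become None.
    """
    out: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sid = row["subject_id"]
            out[sid] = {
                "age": int(row["age"]) if row.get("age") else None,
                "education": int(row["education"]) if row.get("education") else None,
                "gender": row.get("gender") or None,
                "mmse": int(row["mmse"]) if row.get("mmse") else None,
                "label": row.get("label") or UNKNOWN,
            }
    return out


def write_chat(transcript: Transcript, path: str | Path, participant: str = "PAR") -> Path:
    """Serialize a transcript back to a minimal .cha file.

    Inverse of :func:`read_chat` for already-clean token material: the
    file round-trips to identical token sequences.
    """
    path = Path(path)
    label = transcript.label if transcript.label != UNKNOWN else ""
    id_fields = [
        "eng",
        "synthetic",
        participant,
        f"{transcript.age};" if transcript.age is not None else "",
        transcript.gender or "",
        label,
        "",
        "Participant",
        str(transcript.education) if transcript.education is not None else "",
        f"MMSE={transcript.mmse}" if transcript.mmse is not None else "",
    ]
    lines = [
        "@Begin",
        "@Languages:\teng",
        f"@Participants:\t{participant} Participant",
        "@ID:\t" + "|".join(id_fields) + "|",
    ]
    for utt in transcript.utterances:
        lines.append(f"*{participant}:\t" + " ".join(utt.tokens) + " .")
    lines.append("@End")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
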