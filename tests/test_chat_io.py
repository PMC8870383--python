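"""CHAT parsing: participant isolation, symbol stripping, round trips."""
import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cookietalk.chat_io import (
    Transcript,
    Utterance,
    clean_utterance,
    read_chat,
    read_demographics_csv,
    to_plain_text,
    write_chat,
)
from cookietalk.errors import EmptyTranscriptError

FORBIDDEN = re.compile(r"[A-Z\[\]<>&@.,!?]")


def write(tmp_path, text, name="subj01.cha"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadChat:
    def test_investigator_turns_excluded(self, tmp_path):
        path = write(
            tmp_path,
            "@Begin\n"
            "*PAR:\tthe boy is taking a cookie .\n"
            "*INV:\ttell me more .\n"
            "@End\n",
        )
        transcript = read_chat(path)
        assert len(transcript.utterances) == 1
        assert transcript.utterances[0].tokens == (
            "the", "boy", "is", "taking", "a", "cookie",
        )

    def test_dependent_tiers_are_not_speech(self, tmp_path):
        path = write(
            tmp_path,
            "@Begin\n*INV:\tgo ahead .\n%mor:\tdet|the n|boy\n@End\n",
        )
        with pytest.raises(EmptyTranscriptError):
            read_chat(path)

    def test_id_header_demographics(self, tmp_path):
        # hand-parsed oracle: age 67, female, AD group, 12 years education,
        # MMSE 20 from the standard @ID field order
        path = write(
            tmp_path,
            "@Begin\n"
            "@ID:\teng|corpus|PAR|67;|female|ProbableAD||Participant|12|MMSE=20|\n"
            "@ID:\teng|corpus|INV|33;|male|||Investigator||\n"
            "*PAR:\tthe boy is on the stool .\n"
            "@End\n",
        )
        transcript = read_chat(path)
        assert transcript.age == 67
        assert transcript.gender == "female"
        assert transcript.label == "AD"
        assert transcript.education == 12
        assert transcript.mmse == 20

    def test_malformed_id_header_warns(self, tmp_path):
        path = write(tmp_path, "@Begin\n@ID:\tbroken\n*PAR:\thello there .\n@End\n")
        with pytest.warns(UserWarning, match="malformed"):
            transcript = read_chat(path)
        assert transcript.age is None

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_chat(tmp_path / "nope.cha")

    def test_continuation_lines_are_joined(self, tmp_path):
        path = write(tmp_path, "@Begin\n*PAR:\tthe boy is\n\ttaking a cookie .\n@End\n")
        transcript = read_chat(path)
        assert transcript.utterances[0].tokens == (
            "the", "boy", "is", "taking", "a", "cookie",
        )

    def test_sidecar_demographics_override(self, tmp_path):
        path = write(tmp_path, "@Begin\n*PAR:\thello there .\n@End\n")
        csv_path = tmp_path / "demo.csv"
        csv_path.write_text(
            "subject_id,age,education,gender,mmse,label\n"
            "subj01,70,14,male,28,HC\n"
        )
        transcript = read_chat(path, demographics=read_demographics_csv(csv_path))
        assert (transcript.age, transcript.education) == (70, 14)
        assert transcript.mmse == 28 and transcript.label == "HC"


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("the boy [//] the girl is falling .", ["the", "boy", "the", "girl", "is", "falling"]),
        ("&uh the WOMAN .", ["the", "woman"]),
        ("cookie@w .", ["cookie"]),
        ("<the boy> [/] the boy falls .", ["the", "boy", "the", "boy", "falls"]),
        ("she (.) washes (..) dishes .", ["she", "washes", "dishes"]),
        ("(be)cause it fell [* syntax] !", ["because", "it", "fell"]),
        ("", []),
        ("+< xxx [=! laughs] .", ["xxx"]),
    ],
)
def test_clean_utterance(raw, expected):
    assert clean_utterance(raw) == expected


@given(st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126), max_size=60))
def test_clean_utterance_idempotent_and_charset(raw):
    once = clean_utterance(raw)
    assert clean_utterance(" ".join(once)) == once
    for token in once:
        assert not FORBIDDEN.search(token)


class TestPlainText:
    def test_concatenation_preserves_order(self):
        transcript = Transcript(
            "s",
            [
                Utterance("PAR", "", ("the", "boy", "falls")),
                Utterance("PAR", "", ("sink", "overflowing")),
            ],
        )
        plain = to_plain_text(transcript)
        assert plain.tokens == ("the", "boy", "falls", "sink", "overflowing")
        assert plain.text == "the boy falls sink overflowing"
        assert plain.text == " ".join(plain.tokens)

    def test_empty_transcript_rejected(self):
        with pytest.raises(EmptyTranscriptError):
            to_plain_text(Transcript("s", []))


def test_write_read_round_trip(tmp_path):
    transcript = Transcript(
        "rt01",
        [
            Utterance("PAR", "", ("the", "girl", "is", "asking", "for", "a", "cookie")),
            Utterance("PAR", "", ("sink", "overflowing")),
        ],
        age=72,
        education=12,
        gender="female",
        mmse=24,
        label="AD",
    )
    path = write_chat(transcript, tmp_path / "rt01.cha")
    back = read_chat(path)
    assert [u.tokens for u in back.utterances] == [u.tokens for u in transcript.utterances]
    assert (back.age, back.education, back.mmse, back.label) == (72, 12, 24, "AD")


def test_transcript_validation():
    with pytest.raises(ValueError):
        Transcript("s", [], age=-1)
    with pytest.raises(ValueError):
        Transcript("s", [], mmse=31)
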