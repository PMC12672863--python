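"""Transcript normalization and encoding onto the 27-symbol alphabet.

Raw transcript text (plain ``.txt``, a manifest CSV, or minimal CHAT ``.cha``
files) is reduced to a lowercase stream of a-z plus single spaces:
apostrophes are deleted in place so contractions fuse ("don't" -> "dont"),
accented letters are ASCII-folded, and every other non-alphabetic character
becomes a word boundary. The space symbol is deliberately retained — it is
the structural proxy for pausing that the downstream feature screen centers
on — so punctuation maps to space rather than being deleted outright, which
would fuse distinct words and corrupt that signal.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET, Alphabet

logger = logging.getLogger(__name__)

_APOSTROPHES = "'’ʼ‘`"
_NON_ALPHA_RUN = re.compile(r"[^a-z]+")


class TranscriptError(ValueError):
    """Raised when a transcript cannot be normalized, encoded, or read."""


@dataclass
class RawTranscript:
    """Unprocessed transcript text plus corpus metadata."""

    text: str
    transcript_id: str
    participant_id: str
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise TranscriptError("transcript_id must be nonempty")


@dataclass
class CharSequence:
    """A normalized transcript as 0-based indices into the 27-symbol alphabet.

    Invariants: every index lies in [0, 27); no two consecutive space
    indices; no leading or trailing space index.
    """

    indices: np.ndarray
    transcript_id: str
    participant_id: str
    group_label: str = "unknown"
    alphabet: Alphabet = field(default=ALPHABET, repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        k = self.alphabet.size
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= k
        ):
            raise TranscriptError(
                f"{self.transcript_id}: indices outside [0, {k})"
            )

    def __len__(self) -> int:
        return int(self.indices.size)

    def decode(self) -> str:
        """Render the index sequence back to its normalized string."""
        return "".join(self.alphabet.symbols[i] for i in self.indices)

    @property
    def space_fraction(self) -> float:
        """Proportion of whitespace tokens: space count / sequence length."""
        if len(self) == 0:
            raise TranscriptError(f"{self.transcript_id}: empty sequence")
        sp = self.alphabet.space_index
        return float(np.mean(self.indices == sp))


def normalize_text(text: str) -> str:
    """Normalize raw text to lowercase a-z with single internal spaces.

    Rules, applied in order: ASCII-fold accented letters; lowercase; delete
    apostrophes in place (merging the flanking letters, so contractions
    collapse: "don't" -> "dont"); replace every remaining non-alphabetic
    character — punctuation, digits, symbols, newlines — with a space;
    collapse space runs; strip leading/trailing spaces. Total and idempotent.
    """
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.lower()
    for apo in _APOSTROPHES:
        text = text.replace(apo, "")
    text = _NON_ALPHA_RUN.sub(" ", text)
    return text.strip()


def encode(
    text: str,
    alphabet: Alphabet = ALPHABET,
    *,
    transcript_id: str = "",
    participant_id: str = "",
    group_label: str = "unknown",
) -> CharSequence:
    """Encode an already-normalized string to alphabet indices.

    Raises :class:`TranscriptError` if any character falls outside the
    alphabet (i.e. the input was not normalized first).
    """
    try:
        idx = np.fromiter(
            (alphabet.index_of[c] for c in text), dtype=np.int64, count=len(text)
        )
    except KeyError as exc:
        raise TranscriptError(
            f"{transcript_id or '<text>'}: character {exc} not in alphabet; "
            "call normalize_text first"
        ) from None
    return CharSequence(
        indices=idx,
        transcript_id=transcript_id,
        participant_id=participant_id,
        group_label=group_label,
        alphabet=alphabet,
    )


def normalize_and_encode(
    raw: RawTranscript, alphabet: Alphabet = ALPHABET
) -> CharSequence:
    """Normalize a raw transcript and encode it in one step."""
    return encode(
        normalize_text(raw.text),
        alphabet,
        transcript_id=raw.transcript_id,
        participant_id=raw.participant_id,
        group_label=raw.group_label,
    )


# ---------------------------------------------------------------------------
# Corpus reading

_CHA_PAREN = re.compile(r"\([^)]*\)")
_CHA_BRACKET = re.compile(r"\[[^\]]*\]")
_CHA_ANGLE = re.compile(r"[<>]")


def _read_cha(path: Path, speaker: str = "PAR") -> str:
    """Extract the participant speech tier from a minimal CHAT transcript.

    Keeps only ``*PAR:`` main-tier lines (with continuation lines indented by
    a tab), strips bracketed/parenthesized annotation, ``&``-prefixed
    disfluency codes, and trailing time-alignment markers. This is a minimal
    dialect, not a full CHAT parser.
    """
    marker = f"*{speaker}:"
    parts: list[str] = []
    in_tier = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith(marker):
            parts.append(line[len(marker):].strip())
            in_tier = True
        elif in_tier and line.startswith("\t"):
            parts.append(line.strip())
        else:
            in_tier = False
    text = " ".join(parts)
    text = re.sub(r"\x15[^\x15]*\x15", " ", text)  # time alignment
    text = _CHA_PAREN.sub("", text)
    text = _CHA_BRACKET.sub(" ", text)
    text = _CHA_ANGLE.sub(" ", text)
    text = " ".join(tok for tok in text.split() if not tok.startswith("&"))
    return text


def read_transcripts(
    source: str | Path, *, speaker: str = "PAR"
) -> list[RawTranscript]:
    """Read a corpus from a manifest CSV or a directory of .txt/.cha files.

    A manifest CSV must have columns ``path,label,participant_id``; relative
    paths are resolved against the manifest's directory. For a directory,
    every ``.txt``/``.cha`` file becomes one transcript with unknown label
    and the file stem as both transcript and participant id. Missing files
    are skipped with a logged warning; an empty corpus is a hard error.
    """
    source = Path(source)
    records: list[RawTranscript] = []
    if source.is_dir():
        for path in sorted(source.iterdir()):
            if path.suffix not in (".txt", ".cha"):
                continue
            text = (
                _read_cha(path, speaker)
                if path.suffix == ".cha"
                else path.read_text(encoding="utf-8")
            )
            records.append(
                RawTranscript(
                    text=text,
                    transcript_id=path.stem,
                    participant_id=path.stem,
                )
            )
    elif source.is_file():
        with source.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"path", "label", "participant_id"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise TranscriptError(
                    f"manifest {source} must have columns {sorted(required)}"
                )
            for row in reader:
                path = Path(row["path"])
                if not path.is_absolute():
                    path = source.parent / path
                if not path.exists():
                    logger.warning("skipping missing transcript file %s", path)
                    continue
                text = (
                    _read_cha(path, speaker)
                    if path.suffix == ".cha"
                    else path.read_text(encoding="utf-8")
                )
                records.append(
                    RawTranscript(
                        text=text,
                        transcript_id=path.stem,
                        participant_id=row["participant_id"],
                        group_label=row["label"],
                    )
                )
    else:
        raise TranscriptError(f"no such manifest or directory: {source}")
    if not records:
        raise TranscriptError(f"empty corpus: {source}")
    return records


def build_corpus(
    raws: list[RawTranscript], alphabet: Alphabet = ALPHABET
) -> list[CharSequence]:
    """Normalize and encode a list of raw transcripts.

    Transcripts that are empty after normalization admit no transition
    counts; they are excluded with a logged warning rather than zero-filled.
    """
    out: list[CharSequence] = []
    for raw in raws:
        seq = normalize_and_encode(raw, alphabet)
        if len(seq) == 0:
            logger.warning(
                "excluding transcript %s: empty after normalization",
                raw.transcript_id,
            )
            continue
        out.append(seq)
    if not out:
        raise TranscriptError("all transcripts empty after normalization")
    return out
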