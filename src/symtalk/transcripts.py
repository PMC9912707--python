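"""Conversation transcripts as ordered speaker turns, plus tokenization.

The unit of annotation and detection is the *speaker turn*: an uninterrupted
span of speech by one participant.  A conversation is an ordered list of
turns with a conversation id, a patient id, a dataset label (development /
validation / test) and free-form metadata used for stratified evaluation
(e.g. patient self-reported race).

Two on-disk dialects are supported: one structured-text (YAML) document per
conversation, and a flat tabular file with one row per turn.
"""

from __future__ import annotations

import glob
import json
import logging
import os
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SPEAKER_ROLES = ("patient", "clinician", "caregiver", "other")
DATASET_LABELS = ("development", "validation", "test", "user")


class TranscriptError(ValueError):
    """Raised for malformed transcript files."""


@dataclass(frozen=True)
class Turn:
    turn_index: int
    speaker_role: str
    text: str

    def __post_init__(self) -> None:
        if self.speaker_role not in SPEAKER_ROLES:
            raise TranscriptError(
                f"unknown speaker role {self.speaker_role!r} (allowed: {SPEAKER_ROLES})"
            )
        if self.turn_index < 0:
            raise TranscriptError("turn_index must be >= 0")


@dataclass
class Conversation:
    conversation_id: str
    patient_id: str
    turns: list[Turn]
    dataset_label: str = "user"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conversation_id:
            raise TranscriptError("conversation_id is required")
        if not self.patient_id:
            raise TranscriptError(
                f"conversation {self.conversation_id!r} lacks patient ID data"
            )
        if self.dataset_label not in DATASET_LABELS:
            raise TranscriptError(
                f"conversation {self.conversation_id!r}: unknown dataset label "
                f"{self.dataset_label!r}"
            )
        if not self.turns:
            raise TranscriptError(f"conversation {self.conversation_id!r} has no turns")
        indices = [t.turn_index for t in self.turns]
        if indices != list(range(len(self.turns))):
            raise TranscriptError(
                f"conversation {self.conversation_id!r}: turn indices must be "
                "0-based and contiguous"
            )


@dataclass(frozen=True)
class Token:
    text: str          # normalized (lowercased, ASCII quotes) surface form
    start: int         # 0-based char offset into the original turn text
    end: int           # half-open


@dataclass(frozen=True)
class TokenizedTurn:
    turn: Turn
    normalized_text: str
    tokens: tuple[Token, ...]

    @property
    def token_texts(self) -> tuple[str, ...]:
        return tuple(t.text for t in self.tokens)


# Unicode apostrophes / quotes straightened to ASCII so that transcriber
# styling does not affect matching ("don’t" == "don't").
_QUOTE_MAP = {
    "‘": "'", "’": "'", "‚": "'", "ʼ": "'",
    "“": '"', "”": '"', "„": '"',
}

# A token is a maximal run of letters/digits, allowing internal apostrophes
# and hyphens ("don't", "chemo-brain"); spans index the original text.
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:['\-][a-z0-9]+)*")


def normalize_text(text: str) -> str:
    """Lowercase and straighten quotes, preserving string length."""
    out = []
    for ch in text:
        ch = _QUOTE_MAP.get(ch, ch)
        low = ch.lower()
        out.append(low if len(low) == 1 else ch)
    return "".join(out)


def normalize_and_tokenize(turn: Turn) -> TokenizedTurn:
    """Tokenize a turn; token spans are 0-based half-open into the original text."""
    norm = normalize_text(turn.text)
    tokens = tuple(
        Token(text=m.group(0), start=m.start(), end=m.end())
        for m in _TOKEN_RE.finditer(norm)
    )
    return TokenizedTurn(turn=turn, normalized_text=norm, tokens=tokens)


def tokenize_phrase(phrase: str) -> tuple[str, ...]:
    """Word sequence of a (lowercase) library term or exclusion phrase."""
    return tuple(m.group(0) for m in _TOKEN_RE.finditer(normalize_text(phrase)))


# ---------------------------------------------------------------------------
# corpus I/O

def read_corpus(path: str | os.PathLike, format: str | None = None) -> list[Conversation]:
    """Read a corpus from a directory of YAML transcripts or a tabular file.

    Conversations are returned sorted by conversation_id; turn order is
    preserved.  Duplicate conversation ids and missing required fields raise
    :class:`TranscriptError` naming the offending file.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        files = sorted(
            glob.glob(os.path.join(path, "*.yaml")) + glob.glob(os.path.join(path, "*.yml"))
        )
        if not files:
            logger.warning("no transcript files found in %s", path)
            return []
        convs = [read_conversation(f) for f in files]
    else:
        fmt = format or ("structured-text" if path.endswith((".yaml", ".yml")) else "tabular")
        if fmt == "structured-text":
            convs = [read_conversation(path)]
        else:
            convs = _read_tabular_corpus(path)
    seen: set[str] = set()
    for c in convs:
        if c.conversation_id in seen:
            raise TranscriptError(f"duplicate conversation_id {c.conversation_id!r}")
        seen.add(c.conversation_id)
    return sorted(convs, key=lambda c: c.conversation_id)


def read_conversation(path: str | os.PathLike) -> Conversation:
    path = os.fspath(path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise TranscriptError(f"{path}: invalid transcript: {err}") from None
    if not isinstance(doc, dict):
        raise TranscriptError(f"{path}: transcript must be a mapping")
    try:
        raw_turns = doc["turns"]
    except KeyError:
        raise TranscriptError(f"{path}: missing 'turns'") from None
    turns = []
    for i, item in enumerate(raw_turns or []):
        if not isinstance(item, dict) or "speaker_role" not in item:
            raise TranscriptError(f"{path}: turn {i}: missing speaker_role")
        if "text" not in item:
            raise TranscriptError(f"{path}: turn {i}: missing text")
        turns.append(
            Turn(turn_index=int(item.get("turn_index", i)),
                 speaker_role=str(item["speaker_role"]),
                 text=str(item["text"] or ""))
        )
    try:
        return Conversation(
            conversation_id=str(doc.get("conversation_id", "")),
            patient_id=str(doc.get("patient_id") or ""),
            dataset_label=str(doc.get("dataset_label", "user")),
            metadata={str(k): str(v) for k, v in (doc.get("metadata") or {}).items()},
            turns=turns,
        )
    except TranscriptError as err:
        raise TranscriptError(f"{path}: {err}") from None


def write_conversation(conv: Conversation, path: str | os.PathLike) -> None:
    doc = {
        "conversation_id": conv.conversation_id,
        "patient_id": conv.patient_id,
        "dataset_label": conv.dataset_label,
        "metadata": dict(conv.metadata),
        "turns": [
            {"turn_index": t.turn_index, "speaker_role": t.speaker_role, "text": t.text}
            for t in conv.turns
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def write_corpus(corpus: list[Conversation], outdir: str | os.PathLike) -> None:
    """Write one YAML transcript per conversation into ``outdir``."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for conv in corpus:
        write_conversation(conv, os.path.join(outdir, f"{conv.conversation_id}.yaml"))


_TABULAR_COLS = ["conversation_id", "patient_id", "dataset_label", "turn_index",
                 "speaker_role", "text", "metadata"]


def _read_tabular_corpus(path: str) -> list[Conversation]:
    sep = "\t" if path.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    missing = {"conversation_id", "turn_index", "speaker_role", "text"} - set(df.columns)
    if missing:
        raise TranscriptError(f"{path}: missing columns {sorted(missing)}")
    convs = []
    for cid, grp in df.groupby("conversation_id", sort=True):
        grp = grp.sort_values("turn_index", key=lambda s: s.astype(int))
        meta_raw = grp.iloc[0].get("metadata", "") if "metadata" in grp.columns else ""
        metadata = json.loads(meta_raw) if meta_raw else {}
        convs.append(
            Conversation(
                conversation_id=str(cid),
                patient_id=str(grp.iloc[0].get("patient_id", "")),
                dataset_label=str(grp.iloc[0].get("dataset_label", "user") or "user"),
                metadata={str(k): str(v) for k, v in metadata.items()},
                turns=[
                    Turn(turn_index=int(r.turn_index), speaker_role=r.speaker_role,
                         text=r.text)
                    for r in grp.itertuples()
                ],
            )
        )
    return convs


def write_tabular_corpus(corpus: list[Conversation], path: str | os.PathLike) -> None:
    rows = []
    for conv in corpus:
        for t in conv.turns:
            rows.append(
                {
                    "conversation_id": conv.conversation_id,
                    "patient_id": conv.patient_id,
                    "dataset_label": conv.dataset_label,
                    "turn_index": t.turn_index,
                    "speaker_role": t.speaker_role,
                    "text": t.text,
                    "metadata": json.dumps(conv.metadata) if conv.metadata else "",
                }
            )
    sep = "\t" if os.fspath(path).endswith(".tsv") else ","
    pd.DataFrame(rows, columns=_TABULAR_COLS).to_csv(path, sep=sep, index=False)
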