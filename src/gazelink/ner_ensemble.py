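"""Span-level NER utilities: offset-preserving sentence segmentation, IOB
encoding/decoding, and exact-span majority voting over model predictions.

Model inference itself stays behind a file interface — member predictions
arrive as span sets in the annotation TSV dialect — so the voting machinery
is testable without any trained model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .errors import ValidationError
from .kb_io import MentionAnnotation

logger = logging.getLogger(__name__)

# lowercase abbreviations that must not terminate a sentence ("p. ej." etc.)
ABBREVIATIONS = {
    "sr", "sra", "dr", "dra", "ej", "p", "etc", "vs", "fig", "no", "art",
    "approx", "aprox", "vol", "cap", "pag", "tel",
}

_BOUNDARY = re.compile(r"[.!?;](?=\s)|\n")
_TOKEN = re.compile(r"\S+")


@dataclass(frozen=True)
class SentenceSpan:
    doc_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid sentence span [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValidationError("sentence text length does not match its span")


@dataclass(frozen=True)
class IOBSequence:
    """Per-token IOB tags aligned with (surface, start, end) tokens."""

    tokens: tuple[tuple[str, int, int], ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) != len(self.tags):
            raise ValidationError("tokens and tags have different lengths")


@dataclass(frozen=True, order=True)
class PredictedSpan:
    doc_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"invalid predicted span [{self.start}, {self.end})")


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the '.' at dot_pos ends a guarded abbreviation."""
    j = dot_pos - 1
    while j >= 0 and (text[j].isalnum() or text[j] == "_"):
        j -= 1
    word = text[j + 1 : dot_pos].lower()
    return len(word) == 1 and word.isalpha() or word in ABBREVIATIONS


def split_sentences(doc_id: str, text: str) -> list[SentenceSpan]:
    """Segment a document into sentences, preserving character offsets.

    Boundaries fall after sentence-final punctuation (. ! ? ;) followed by
    whitespace, and at newlines; periods after single letters or known
    clinical abbreviations do not split. Sentences are trimmed of surrounding
    whitespace, so the skipped separators (all whitespace) plus the sentence
    texts reconstruct the document.
    """
    if not text:
        raise ValidationError("cannot split an empty document")
    cut_points = [0]
    for match in _BOUNDARY.finditer(text):
        if text[match.start()] == "." and _is_abbreviation(text, match.start()):
            continue
        cut_points.append(match.end())
    cut_points.append(len(text))

    spans: list[SentenceSpan] = []
    for lo, hi in zip(cut_points, cut_points[1:]):
        chunk = text[lo:hi]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = lo + chunk.index(stripped[0])
        end = start + len(stripped)
        # re-slice instead of using `stripped` so internal offsets are exact
        spans.append(SentenceSpan(doc_id=doc_id, start=start, end=end, text=text[start:end]))
    return spans


def whitespace_tokenize(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Tokenize on whitespace, emitting (surface, start, end) with offsets
    shifted by ``offset`` (use the sentence start for document-level spans)."""
    return [(m.group(), m.start() + offset, m.end() + offset) for m in _TOKEN.finditer(text)]


def to_iob(
    sentence: SentenceSpan,
    mentions: Sequence[MentionAnnotation],
    tokenizer: Callable[[str, int], list[tuple[str, int, int]]] = whitespace_tokenize,
) -> IOBSequence:
    """Encode the mentions inside a sentence as per-token IOB tags.

    A token overlapping a mention span by any amount belongs to the mention
    (first token B-label, rest I-label). Overlapping gold mentions raise a
    :class:`ValidationError` naming the pair.
    """
    inside = [m for m in mentions if m.start < sentence.end and m.end > sentence.start]
    ordered = sorted(inside, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"overlapping mentions [{a.start},{a.end}) {a.text!r} and "
                f"[{b.start},{b.end}) {b.text!r}"
            )
    tokens = tuple(tokenizer(sentence.text, sentence.start))
    tags: list[str] = []
    prev_mention: MentionAnnotation | None = None
    for _, tok_start, tok_end in tokens:
        hit = next((m for m in ordered if tok_start < m.end and tok_end > m.start), None)
        if hit is None:
            tags.append("O")
        elif hit is prev_mention:
            tags.append(f"I-{hit.label}")
        else:
            tags.append(f"B-{hit.label}")
        prev_mention = hit
    return IOBSequence(tokens=tokens, tags=tuple(tags))


def from_iob(seq: IOBSequence, sentence: SentenceSpan) -> list[PredictedSpan]:
    """Decode IOB tags back into document-level spans.

    Maximal B/I runs of one label become spans. An orphan I tag (no matching
    B or I before it) is repaired to B with a logged warning.
    """
    spans: list[PredictedSpan] = []
    current_label: str | None = None
    current_start = current_end = 0
    for (surface, tok_start, tok_end), tag in zip(seq.tokens, seq.tags):
        if tag == "O":
            if current_label is not None:
                spans.append(PredictedSpan(sentence.doc_id, current_start, current_end, current_label))
                current_label = None
            continue
        prefix, label = tag.split("-", 1)
        if prefix == "I" and current_label != label:
            logger.warning("orphan I-%s at %r repaired to B-%s", label, surface, label)
            prefix = "B"
        if prefix == "B":
            if current_label is not None:
                spans.append(PredictedSpan(sentence.doc_id, current_start, current_end, current_label))
            current_label = label
            current_start = tok_start
        current_end = tok_end
    if current_label is not None:
        spans.append(PredictedSpan(sentence.doc_id, current_start, current_end, current_label))
    return spans


def majority_vote(
    predictions: Sequence[Iterable[PredictedSpan]],
    min_votes: int | None = None,
) -> set[PredictedSpan]:
    """Keep each exactly-matched span that appears in at least ``min_votes``
    member prediction sets (default: strict majority, floor(M/2) + 1)."""
    m = len(predictions)
    if m < 1:
        raise ValidationError("majority_vote needs at least one member")
    if min_votes is None:
        min_votes = m // 2 + 1
    if not (1 <= min_votes <= m):
        raise ValidationError(f"min_votes must be in [1, {m}], got {min_votes}")
    counts: dict[PredictedSpan, int] = {}
    for member in predictions:
        for span in set(member):
            counts[span] = counts.get(span, 0) + 1
    return {span for span, votes in counts.items() if votes >= min_votes}


def spans_from_annotations(mentions: Iterable[MentionAnnotation]) -> set[PredictedSpan]:
    """Project annotations to bare (doc_id, start, end, label) spans."""
    return {PredictedSpan(m.doc_id, m.start, m.end, m.label) for m in mentions}


__all__ = [
    "ABBREVIATIONS",
    "SentenceSpan",
    "IOBSequence",
    "PredictedSpan",
    "split_sentences",
    "whitespace_tokenize",
    "to_iob",
    "from_iob",
    "majority_vote",
    "spans_from_annotations",
]
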