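"""Gazetteer and mention-annotation I/O, training-set construction, splits.

File dialects (tab-separated, UTF-8, one header row):

* gazetteer: columns ``code``, ``language``, ``term``, ``semantic_tag``,
  ``mainterm`` (``mainterm`` is ``1``/``0``);
* annotations: columns ``filename``, ``label``, ``start_span``, ``end_span``,
  ``text`` and, when codes are present, a trailing ``code`` column holding
  ``+``-joined concept identifiers or the sentinel ``NO_CODE``.

Character offsets are 0-based, half-open.
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

NO_CODE = "NO_CODE"
COMPOSITE_SEP = "+"

GAZETTEER_COLUMNS = ("code", "language", "term", "semantic_tag", "mainterm")
ANNOTATION_COLUMNS = ("filename", "label", "start_span", "end_span", "text")


@dataclass(frozen=True)
class GazetteerEntry:
    """One surface term mapped to one concept code."""

    code: str
    term: str
    semantic_tag: str = ""
    language: str = "es"
    is_main_term: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", self.code.strip())
        object.__setattr__(self, "term", self.term.strip())
        if not self.code:
            raise ValidationError("gazetteer entry has an empty code")
        if not self.term:
            raise ValidationError(
                f"gazetteer entry for code {self.code!r} has an empty term"
            )


@dataclass(frozen=True)
class MentionAnnotation:
    """A character-span entity mention in a document.

    ``codes`` holds the linked concept identifiers in input order; an empty
    list marks an uncoded mention and more than one element a composite one.
    """

    doc_id: str
    start: int
    end: int
    text: str
    label: str
    codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span [{self.start}, {self.end}) in {self.doc_id!r}"
            )
        if len(self.text) != self.end - self.start:
            raise ValidationError(
                f"text length {len(self.text)} does not match span "
                f"[{self.start}, {self.end}) in {self.doc_id!r}"
            )
        object.__setattr__(self, "codes", tuple(self.codes))


@dataclass(frozen=True)
class TrainingEntry:
    """A (surface, code) training pair; surface may carry a ``[tag]`` suffix."""

    surface: str
    code: str
    source: str = "gazetteer"  # "mention" | "gazetteer"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("training entry has an empty surface")
        if self.source not in ("mention", "gazetteer"):
            raise ValidationError(f"unknown training-entry source {self.source!r}")


def _open_reader(path: Path) -> Iterable[list[str]]:
    with path.open("r", encoding="utf-8", newline="") as handle:
        yield from csv.reader(handle, delimiter="\t")


def load_gazetteer(path: str | Path) -> list[GazetteerEntry]:
    """Parse a gazetteer TSV into entries, collapsing duplicate rows.

    Duplicates are keyed on (code, term, language); each collapse is logged
    as a warning. Raises :class:`FormatError` when a required column is
    missing and :class:`ValidationError` (with the line number) when a row
    has an empty code or term.
    """
    path = Path(path)
    rows = _open_reader(path)
    try:
        header = next(iter(rows))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in GAZETTEER_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    idx = {name: header.index(name) for name in GAZETTEER_COLUMNS}

    entries: list[GazetteerEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        try:
            entry = GazetteerEntry(
                code=row[idx["code"]],
                term=row[idx["term"]],
                semantic_tag=row[idx["semantic_tag"]].strip(),
                language=row[idx["language"]].strip(),
                is_main_term=row[idx["mainterm"]].strip() in ("1", "true", "True"),
            )
        except (IndexError, ValidationError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
        key = (entry.code, entry.term, entry.language)
        if key in seen:
            logger.warning("%s:%d: duplicate gazetteer row %s collapsed", path, lineno, key)
            continue
        seen.add(key)
        entries.append(entry)
    return entries


def write_gazetteer(entries: Iterable[GazetteerEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(GAZETTEER_COLUMNS)
        for e in entries:
            writer.writerow(
                [e.code, e.language, e.term, e.semantic_tag, "1" if e.is_main_term else "0"]
            )


def load_annotations(path: str | Path, with_codes: bool = False) -> list[MentionAnnotation]:
    """Parse a mention-annotation TSV.

    With ``with_codes`` the trailing ``code`` column is required; the string
    ``"A+B"`` becomes ``codes=("A", "B")`` and the sentinel :data:`NO_CODE`
    yields an empty code tuple.
    """
    path = Path(path)
    rows = _open_reader(path)
    try:
        header = next(iter(rows))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    required = ANNOTATION_COLUMNS + (("code",) if with_codes else ())
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    idx = {name: header.index(name) for name in required}

    mentions: list[MentionAnnotation] = []
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not f.strip() for f in row):
            continue
        try:
            start = int(row[idx["start_span"]])
            end = int(row[idx["end_span"]])
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{lineno}: non-integer character offsets") from None
        codes: tuple[str, ...] = ()
        if with_codes:
            raw = row[idx["code"]].strip()
            if raw and raw != NO_CODE:
                codes = tuple(c.strip() for c in raw.split(COMPOSITE_SEP) if c.strip())
        try:
            mentions.append(
                MentionAnnotation(
                    doc_id=row[idx["filename"]],
                    start=start,
                    end=end,
                    text=row[idx["text"]],
                    label=row[idx["label"]],
                    codes=codes,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return mentions


def write_annotations(
    mentions: Iterable[MentionAnnotation], path: str | Path, with_codes: bool = False
) -> None:
    path = Path(path)
    header = list(ANNOTATION_COLUMNS) + (["code"] if with_codes else [])
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for m in mentions:
            row = [m.doc_id, m.label, str(m.start), str(m.end), m.text]
            if with_codes:
                row.append(COMPOSITE_SEP.join(m.codes) if m.codes else NO_CODE)
            writer.writerow(row)


def format_training_term(term: str, semantic_tag: str) -> str:
    """Append the ``[semantic_tag]`` suffix to a surface term.

    Returns the term unchanged when the tag is empty; the suffix is appended
    verbatim, with no escaping of brackets already present in the term.
    """
    if not term:
        raise ValidationError("cannot format an empty term")
    if not semantic_tag:
        return term
    return f"{term} [{semantic_tag}]"


def build_training_set(
    mentions: Sequence[MentionAnnotation],
    gazetteer: Sequence[GazetteerEntry],
    tag_lookup: Mapping[str, str] | None = None,
) -> list[TrainingEntry]:
    """Concatenate coded mentions with the full gazetteer into training pairs.

    Mentions come first, then gazetteer entries, each preserving input order.
    A composite mention contributes one pair under its first code. Surfaces
    are tag-suffixed via :func:`format_training_term`; mention tags come from
    ``tag_lookup`` (codes absent from the lookup get empty-tag formatting).
    """
    tag_lookup = tag_lookup or {}
    out: list[TrainingEntry] = []
    for m in mentions:
        if not m.codes:
            raise ValidationError(
                f"uncoded mention {m.text!r} in {m.doc_id!r}; remove uncoded "
                "mentions before building the training set"
            )
        code = m.codes[0]
        out.append(
            TrainingEntry(
                surface=format_training_term(m.text, tag_lookup.get(code, "")),
                code=code,
                source="mention",
            )
        )
    for e in gazetteer:
        out.append(
            TrainingEntry(
                surface=format_training_term(e.term, e.semantic_tag),
                code=e.code,
                source="gazetteer",
            )
        )
    return out


def tag_lookup_from_gazetteer(gazetteer: Iterable[GazetteerEntry]) -> dict[str, str]:
    """Map each code to the first non-empty semantic tag seen for it."""
    lookup: dict[str, str] = {}
    for e in gazetteer:
        if e.semantic_tag and e.code not in lookup:
            lookup[e.code] = e.semantic_tag
    return lookup


def stratified_split(
    mentions: Sequence[MentionAnnotation],
    val_fraction: float,
    seed: int,
) -> tuple[list[MentionAnnotation], list[MentionAnnotation]]:
    """Split coded mentions into train/validation, stratifying by first code.

    For a code with n >= 2 mentions, round-half-up(n * val_fraction) go to
    validation, capped so at least one stays in train; singleton codes stay
    entirely in train. Selection within a code is a seeded uniform draw, so
    identical seeds give identical partitions.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValidationError(f"val_fraction must be in (0, 1), got {val_fraction}")
    by_code: dict[str, list[int]] = {}
    for i, m in enumerate(mentions):
        if not m.codes:
            raise ValidationError(
                f"mention {m.text!r} in {m.doc_id!r} has no code; "
                "stratified_split requires coded mentions"
            )
        by_code.setdefault(m.codes[0], []).append(i)

    rng = random.Random(seed)
    val_idx: set[int] = set()
    for code in sorted(by_code):
        idxs = by_code[code]
        n = len(idxs)
        if n < 2:
            continue
        # round-half-up, never emptying the train side
        n_val = min(int(n * val_fraction + 0.5), n - 1)
        if n_val > 0:
            val_idx.update(rng.sample(idxs, n_val))

    train = [m for i, m in enumerate(mentions) if i not in val_idx]
    val = [m for i, m in enumerate(mentions) if i in val_idx]
    return train, val


__all__ = [
    "NO_CODE",
    "GazetteerEntry",
    "MentionAnnotation",
    "TrainingEntry",
    "load_gazetteer",
    "write_gazetteer",
    "load_annotations",
    "write_annotations",
    "format_training_term",
    "build_training_set",
    "tag_lookup_from_gazetteer",
    "stratified_split",
]
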