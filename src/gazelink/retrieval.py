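"""Dense candidate generation: exact cosine search over gazetteer terms.

The index stores one l2-normalized row per term. Retrieval scores every row,
lifts term similarities to concept codes by taking the max over each code's
rows, and returns codes ranked by score (ties broken lexicographically by
code). Exact exhaustive search is the reference implementation; approximate
backends must reproduce it at recall 1.0 on small indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .embedding import EmbeddingBackend, embed_terms, l2_normalize
from .errors import ValidationError
from .kb_io import GazetteerEntry, TrainingEntry


@dataclass(frozen=True)
class CandidateList:
    """Ranked, per-code-deduplicated (code, score) pairs."""

    items: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple((c, float(s)) for c, s in self.items))
        scores = [s for _, s in self.items]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValidationError("candidate scores must be non-increasing")
        codes = [c for c, _ in self.items]
        if len(set(codes)) != len(codes):
            raise ValidationError("candidate codes must be pairwise distinct")

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


@dataclass(frozen=True)
class TermIndex:
    """All gazetteer term embeddings, row-aligned with codes and surfaces."""

    vectors: np.ndarray
    codes: tuple[str, ...]
    surfaces: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        object.__setattr__(self, "surfaces", tuple(self.surfaces))
        if not (len(self.codes) == len(self.surfaces) == self.vectors.shape[0]):
            raise ValidationError("index rows, codes and surfaces are misaligned")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("index rows must be unit-norm")

    @property
    def n_terms(self) -> int:
        return int(self.vectors.shape[0])


def _entry_surface(entry: Union[GazetteerEntry, TrainingEntry]) -> str:
    return entry.term if isinstance(entry, GazetteerEntry) else entry.surface


def build_index(
    entries: Sequence[Union[GazetteerEntry, TrainingEntry]],
    backend: EmbeddingBackend,
) -> TermIndex:
    """Embed every entry surface and assemble a unit-row term index."""
    if not entries:
        raise ValidationError("cannot build an index from zero entries")
    surfaces = [_entry_surface(e) for e in entries]
    vectors = l2_normalize(embed_terms(backend, surfaces))
    return TermIndex(
        vectors=vectors,
        codes=tuple(e.code for e in entries),
        surfaces=tuple(surfaces),
    )


def retrieve(index: TermIndex, mention_vec: np.ndarray, k: int) -> CandidateList:
    """Return the top-k most similar concepts for one mention vector.

    Each code's score is the max cosine over its term rows; codes are ranked
    by score descending with lexicographic tie-break. Fewer than k items are
    returned when the index holds fewer distinct codes.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    q = l2_normalize(np.asarray(mention_vec, dtype=np.float64).ravel())
    sims = index.vectors @ q
    best: dict[str, float] = {}
    for code, sim in zip(index.codes, sims):
        s = float(sim)
        if code not in best or s > best[code]:
            best[code] = s
    ranked = sorted(best.items(), key=lambda cs: (-cs[1], cs[0]))
    return CandidateList(items=tuple(ranked[:k]))


def link_batch(
    index: TermIndex,
    mentions: Sequence[str],
    backend: EmbeddingBackend,
    k: int,
) -> list[CandidateList]:
    """Embed mention surfaces and retrieve candidates for each, in order."""
    vectors = embed_terms(backend, list(mentions))
    return [retrieve(index, vectors[i], k) for i in range(len(mentions))]


__all__ = ["TermIndex", "CandidateList", "build_index", "retrieve", "link_batch"]
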