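"""Embedding-backend contract and a deterministic character-n-gram backend.

Every component of the package is parameterized by an object satisfying
:class:`EmbeddingBackend`: it exposes ``dim`` and ``embed_batch`` and must be
deterministic within a process, never returning an all-zero row for a
non-empty input. The shipped :class:`HashNgramBackend` is a desk-scale
stand-in for a frozen transformer bi-encoder; adapters wrapping external
encoders only need to honor the same contract.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import ValidationError

DEFAULT_DIM = 256
DEFAULT_NGRAM_RANGE = (2, 4)
DEFAULT_SEED = 13


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for anything that turns strings into fixed-width vectors."""

    @property
    def dim(self) -> int: ...

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray: ...


def _ngrams(text: str, n_low: int, n_high: int) -> Iterable[str]:
    padded = f"#{text.lower()}#"
    for n in range(n_low, n_high + 1):
        for i in range(len(padded) - n + 1):
            yield padded[i : i + n]


def hash_ngram_embed(
    texts: Sequence[str],
    dim: int = DEFAULT_DIM,
    n_range: tuple[int, int] = DEFAULT_NGRAM_RANGE,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Embed texts as signed counts of hashed character n-grams.

    Each text is lowercased, padded with ``#`` boundary markers and
    decomposed into character n-grams; each n-gram is hashed (keyed by the
    seed) to one of ``dim`` coordinates with a +/-1 sign. Identical texts
    always map to identical rows.
    """
    n_low, n_high = n_range
    if dim < 8:
        raise ValidationError(f"dim must be >= 8, got {dim}")
    if not (1 <= n_low <= n_high <= 5):
        raise ValidationError(f"n_range must satisfy 1 <= low <= high <= 5, got {n_range}")
    key = str(seed).encode("utf-8")
    out = np.zeros((len(texts), dim), dtype=np.float64)
    for row, text in enumerate(texts):
        if not text:
            raise ValidationError(f"cannot embed empty string at position {row}")
        for gram in _ngrams(text, n_low, n_high):
            digest = hashlib.blake2b(gram.encode("utf-8"), key=key, digest_size=8).digest()
            value = int.from_bytes(digest, "little")
            coord = (value >> 1) % dim
            sign = 1.0 if value & 1 else -1.0
            out[row, coord] += sign
        if not out[row].any():  # contract: non-empty input must not be a zero row
            raise ValidationError(f"text {text!r} hashed to an all-zero row")
    return out


class HashNgramBackend:
    """Deterministic hashing embedder satisfying :class:`EmbeddingBackend`."""

    def __init__(
        self,
        dim: int = DEFAULT_DIM,
        n_range: tuple[int, int] = DEFAULT_NGRAM_RANGE,
        seed: int = DEFAULT_SEED,
    ) -> None:
        if dim < 8:
            raise ValidationError(f"dim must be >= 8, got {dim}")
        self._dim = dim
        self._n_range = n_range
        self._seed = seed

    @property
    def dim(self) -> int:
        return self._dim

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        return hash_ngram_embed(texts, self._dim, self._n_range, self._seed)


class LookupBackend:
    """Backend returning pre-computed (planted) vectors by exact surface match.

    Used by the synthetic-data tests to decouple embedding geometry from any
    particular string embedder.
    """

    def __init__(self, surfaces: Sequence[str], vectors: np.ndarray) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if len(surfaces) != vectors.shape[0]:
            raise ValidationError("surfaces and vectors are misaligned")
        self._table = {s: vectors[i] for i, s in enumerate(surfaces)}
        self._dim = int(vectors.shape[1])

    @property
    def dim(self) -> int:
        return self._dim

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        try:
            return np.stack([self._table[t] for t in texts])
        except KeyError as exc:
            raise ValidationError(f"surface {exc.args[0]!r} has no planted vector") from None


def l2_normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Scale vectors (or matrix rows) to unit Euclidean norm.

    Raises :class:`ValidationError` on any zero vector.
    """
    v = np.asarray(v, dtype=np.float64)
    norms = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("cannot l2-normalize a zero vector")
    return v / norms


def embed_terms(
    backend: EmbeddingBackend,
    surfaces: Sequence[str],
    batch_size: int = 256,
) -> np.ndarray:
    """Embed surfaces in batches; the result is independent of batch size."""
    if not surfaces:
        raise ValidationError("embed_terms requires at least one surface")
    if batch_size < 1:
        raise ValidationError(f"batch_size must be positive, got {batch_size}")
    chunks = []
    for start in range(0, len(surfaces), batch_size):
        batch = list(surfaces[start : start + batch_size])
        try:
            chunks.append(np.asarray(backend.embed_batch(batch), dtype=np.float64))
        except Exception as exc:
            exc.add_note(f"backend failed on batch starting at surface index {start}")
            raise
    return np.vstack(chunks)


def save_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited text: ``n dim`` then n rows.

    Values are printed with 17 significant digits, enough for an exact
    float64 round-trip.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for row in matrix:
            handle.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def load_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise ValidationError(f"{path}: malformed matrix header")
        n, dim = int(header[0]), int(header[1])
        matrix = np.loadtxt(handle, dtype=np.float64, ndmin=2)
    if matrix.shape != (n, dim):
        raise ValidationError(
            f"{path}: header promises {(n, dim)}, file holds {matrix.shape}"
        )
    return matrix


__all__ = [
    "EmbeddingBackend",
    "HashNgramBackend",
    "LookupBackend",
    "hash_ngram_embed",
    "l2_normalize",
    "embed_terms",
    "save_matrix",
    "load_matrix",
]
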