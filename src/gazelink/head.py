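"""Temperature-scaled cosine-softmax classification head over frozen embeddings.

The head holds one weight row per concept. Rows are initialized as the
arithmetic mean of the raw embeddings of every training surface mapped to
that concept, so a freshly initialized head is exactly a nearest-centroid
classifier under cosine similarity. Logits are cosines between the (call-time
l2-normalized) weight rows and the mention embedding; posteriors divide the
cosines by a temperature before a stabilized softmax. Fine-tuning runs
deterministic mini-batch gradient descent on the weight matrix only — the
embeddings are fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingBackend, embed_terms, l2_normalize, load_matrix, save_matrix
from .errors import InitializationError, TrainingError, ValidationError
from .kb_io import TrainingEntry
from .retrieval import CandidateList

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 0.05


@dataclass
class CosineSoftmaxHead:
    """Per-concept weight matrix with an ordered concept inventory and a
    softmax temperature. Rows are stored raw; normalization happens inside
    :func:`logits` so the centroid initialization stays exact."""

    weights: np.ndarray
    concept_order: tuple[str, ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.concept_order = tuple(self.concept_order)
        if self.weights.ndim != 2 or self.weights.shape[0] != len(self.concept_order):
            raise ValidationError("weight rows and concept_order are misaligned")
        if len(set(self.concept_order)) != len(self.concept_order):
            raise ValidationError("concept_order contains duplicates")
        if not len(self.concept_order):
            raise ValidationError("head needs at least one concept")
        if not np.isfinite(self.weights).all():
            raise ValidationError("head weights must be finite")
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be positive, got {self.temperature}")

    @property
    def n_concepts(self) -> int:
        return len(self.concept_order)

    @property
    def dim(self) -> int:
        return int(self.weights.shape[1])

    def copy(self) -> "CosineSoftmaxHead":
        return CosineSoftmaxHead(self.weights.copy(), self.concept_order, self.temperature)


@dataclass(frozen=True)
class HeadTrainConfig:
    learning_rate: float = 3e-4
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    patience: int = 3  # early stop after this many non-improving epochs; 0 disables

    def __post_init__(self) -> None:
        if not (1e-6 <= self.learning_rate <= 1e-1) and self.learning_rate != 0.0:
            raise ValidationError(
                f"learning_rate must be 0 or in [1e-6, 1e-1], got {self.learning_rate}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")


def init_head(
    training_entries: Sequence[TrainingEntry],
    backend: EmbeddingBackend,
    temperature: float = DEFAULT_TEMPERATURE,
) -> CosineSoftmaxHead:
    """Build a head whose row for each concept is the mean raw embedding of
    all training surfaces carrying that concept's code.

    The concept inventory is the sorted set of distinct codes. Raises
    :class:`InitializationError` naming the code if any mean embedding is the
    zero vector.
    """
    if not training_entries:
        raise ValidationError("init_head requires at least one training entry")
    vectors = embed_terms(backend, [e.surface for e in training_entries])
    codes = sorted({e.code for e in training_entries})
    code_to_row = {c: i for i, c in enumerate(codes)}
    sums = np.zeros((len(codes), vectors.shape[1]), dtype=np.float64)
    counts = np.zeros(len(codes), dtype=np.int64)
    for entry, vec in zip(training_entries, vectors):
        row = code_to_row[entry.code]
        sums[row] += vec
        counts[row] += 1
    means = sums / counts[:, None]
    zero_rows = np.flatnonzero(~means.any(axis=1))
    if zero_rows.size:
        raise InitializationError(
            f"mean embedding is the zero vector for code {codes[int(zero_rows[0])]!r}"
        )
    return CosineSoftmaxHead(weights=means, concept_order=tuple(codes), temperature=temperature)


def logits(head: CosineSoftmaxHead, mention_vec: np.ndarray) -> np.ndarray:
    """Cosine similarities between each (normalized) weight row and the
    normalized mention vector; entries lie in [-1, 1]."""
    q = l2_normalize(np.asarray(mention_vec, dtype=np.float64).ravel())
    w = l2_normalize(head.weights, axis=1)
    return w @ q


def posterior(head: CosineSoftmaxHead, mention_vec: np.ndarray) -> np.ndarray:
    """Softmax of the cosine logits divided by the temperature.

    Computed with max-subtraction, so entries are in (0, 1) and sum to 1
    within 1e-9 for any finite input.
    """
    return softmax_with_temperature(logits(head, mention_vec), head.temperature)


def softmax_with_temperature(scores: np.ndarray, temperature: float) -> np.ndarray:
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    z = np.asarray(scores, dtype=np.float64) / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def predict_topk(head: CosineSoftmaxHead, mention_vec: np.ndarray, k: int) -> CandidateList:
    """Rank concepts by posterior (equivalently by cosine logit), with
    lexicographic tie-break on the code; scores are posteriors."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    p = posterior(head, mention_vec)
    order = sorted(range(head.n_concepts), key=lambda i: (-p[i], head.concept_order[i]))
    top = order[:k]
    return CandidateList(items=tuple((head.concept_order[i], float(p[i])) for i in top))


def predict_batch_topk(
    head: CosineSoftmaxHead, mention_vecs: np.ndarray, k: int
) -> list[CandidateList]:
    vecs = np.atleast_2d(np.asarray(mention_vecs, dtype=np.float64))
    return [predict_topk(head, vecs[i], k) for i in range(vecs.shape[0])]


def _cross_entropy_and_grad(
    weights: np.ndarray,
    x_unit: np.ndarray,
    label_rows: np.ndarray,
    temperature: float,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of the temperature softmax over a batch, and its
    gradient with respect to the raw weight rows."""
    b = x_unit.shape[0]
    norms = np.linalg.norm(weights, axis=1, keepdims=True)
    w_unit = weights / norms
    s = x_unit @ w_unit.T  # (b, n) cosines
    z = s / temperature
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    nll = -np.log(p[np.arange(b), label_rows] + 1e-300)
    loss = float(nll.mean())

    dl_ds = p.copy()
    dl_ds[np.arange(b), label_rows] -= 1.0
    dl_ds /= temperature * b
    # s_{ji} = x̂_j · ŵ_i ; ∂s_{ji}/∂w_i = (x̂_j − s_{ji} ŵ_i) / ‖w_i‖
    grad = dl_ds.T @ x_unit - ((dl_ds * s).sum(axis=0)[:, None]) * w_unit
    grad /= norms
    return loss, grad


def finetune(
    head: CosineSoftmaxHead,
    mention_vecs: np.ndarray,
    labels: Sequence[str],
    config: HeadTrainConfig,
) -> tuple[CosineSoftmaxHead, list[float]]:
    """Fine-tune the weight matrix by mini-batch gradient descent on the mean
    cross-entropy of the temperature-softmax posteriors.

    Embeddings are fixed inputs; only the weights move. Shuffling is seeded
    per epoch, so identical configs and inputs yield bit-identical weights.
    Returns the tuned head (a copy) and the per-epoch mean loss trace.
    Stops early after ``config.patience`` consecutive non-improving epochs.
    """
    vecs = np.atleast_2d(np.asarray(mention_vecs, dtype=np.float64))
    if vecs.shape[0] != len(labels):
        raise ValidationError("mention_vecs row count must equal len(labels)")
    row_of = {c: i for i, c in enumerate(head.concept_order)}
    try:
        label_rows = np.array([row_of[c] for c in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} is not in the concept inventory") from None

    x_unit = l2_normalize(vecs, axis=1)
    tuned = head.copy()
    rng = np.random.default_rng(config.seed)
    n = vecs.shape[0]
    trace: list[float] = []
    best_loss = np.inf
    stale = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            loss, grad = _cross_entropy_and_grad(
                tuned.weights, x_unit[batch], label_rows[batch], tuned.temperature
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at batch starting {start}")
            loss_sum += loss * len(batch)
            if config.learning_rate:
                tuned.weights = tuned.weights - config.learning_rate * grad
        epoch_loss = loss_sum / n
        trace.append(epoch_loss)
        if epoch_loss < best_loss - 1e-12:
            best_loss = epoch_loss
            stale = 0
        else:
            stale += 1
            if config.patience and stale >= config.patience:
                logger.info("early stop after %d epochs (patience %d)", len(trace), config.patience)
                break
    return tuned, trace


def save_head(head: CosineSoftmaxHead, path: str | Path) -> None:
    """Serialize a head as text: a config header, the concept inventory, and
    the weight matrix in the package's matrix text format. Exact round-trip."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write(f"temperature {head.temperature:.17g}\n")
        handle.write(f"concepts {head.n_concepts}\n")
        for code in head.concept_order:
            handle.write(code + "\n")
    matrix_path = path.with_suffix(path.suffix + ".mat")
    save_matrix(head.weights, matrix_path)


def load_head(path: str | Path) -> CosineSoftmaxHead:
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        tau_line = handle.readline().split()
        count_line = handle.readline().split()
        if tau_line[:1] != ["temperature"] or count_line[:1] != ["concepts"]:
            raise ValidationError(f"{path}: malformed head header")
        temperature = float(tau_line[1])
        n = int(count_line[1])
        concepts = tuple(handle.readline().rstrip("\n") for _ in range(n))
    weights = load_matrix(path.with_suffix(path.suffix + ".mat"))
    return CosineSoftmaxHead(weights=weights, concept_order=concepts, temperature=temperature)


__all__ = [
    "DEFAULT_TEMPERATURE",
    "CosineSoftmaxHead",
    "HeadTrainConfig",
    "init_head",
    "logits",
    "posterior",
    "softmax_with_temperature",
    "predict_topk",
    "predict_batch_topk",
    "finetune",
    "save_head",
    "load_head",
]
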