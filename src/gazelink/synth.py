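"""Synthetic gazetteers, mentions, documents, and embedding geometries.

Everything is planted: each concept owns a latent unit direction, gazetteer
synonym vectors are the latent plus term noise, mention vectors are the
latent plus (larger) mention noise. Tests pair the generated surfaces with
their planted vectors through a lookup backend, so geometry is decoupled
from any particular string embedder. All draws are seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import LookupBackend, l2_normalize
from .errors import ValidationError
from .kb_io import GazetteerEntry, MentionAnnotation
from .ner_ensemble import PredictedSpan, whitespace_tokenize

DEFAULT_TAGS = ("finding", "disorder", "morphologic abnormality")

# sub-stream ids, so each generator draws from an independent seeded stream
_STREAM_GEOMETRY = 1
_STREAM_GAZETTEER = 2
_STREAM_MENTIONS = {"train": 3, "val": 4, "test": 5}
_STREAM_NER = 6


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-embedding generator.

    Noise vectors are drawn from a shared anisotropic Gaussian: per-coordinate
    standard deviation sigma / sqrt(dim), boosted by ``noise_boost`` on
    ``noisy_dims`` randomly rotated nuisance axes that all concepts share.
    The nuisance subspace is what makes discriminative fine-tuning of the
    softmax head genuinely better than its nearest-centroid initialization:
    a per-concept mean cannot down-weight high-variance directions, a trained
    weight matrix can.
    """

    n_concepts: int = 200
    dim: int = 64
    synonyms_mean: float = 3.0  # mean of 1 + Poisson(synonyms_mean - 1)
    mentions_per_concept_train: int = 20
    mentions_per_concept_val: int = 5
    mentions_per_concept_test: int = 5
    term_noise_sd: float = 0.3
    mention_noise_sd: float = 0.6
    zero_shot_fraction: float = 0.0
    noisy_dims: int = 8
    noise_boost: float = 8.0
    tag_set: tuple[str, ...] = DEFAULT_TAGS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("n_concepts must be >= 2")
        if self.dim < 8:
            raise ValidationError("dim must be >= 8")
        if self.synonyms_mean < 1:
            raise ValidationError("synonyms_mean must be >= 1")
        if self.term_noise_sd < 0 or self.mention_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        if not (0.0 <= self.zero_shot_fraction < 1.0):
            raise ValidationError("zero_shot_fraction must be in [0, 1)")
        if not (0 <= self.noisy_dims <= self.dim):
            raise ValidationError("noisy_dims must be in [0, dim]")
        if self.noise_boost < 1.0:
            raise ValidationError("noise_boost must be >= 1")
        if not self.tag_set:
            raise ValidationError("tag_set must be non-empty")


@dataclass(frozen=True)
class ConceptGeometry:
    """Latent unit direction, code and semantic tag for every concept, plus
    the shared noise transform mapping standard-normal draws to perturbations."""

    latent: np.ndarray
    codes: tuple[str, ...]
    tags: tuple[str, ...]
    noise_transform: np.ndarray  # (dim, dim); perturbation = sigma * z @ transform

    def __post_init__(self) -> None:
        if not (self.latent.shape[0] == len(self.codes) == len(self.tags)):
            raise ValidationError("geometry rows, codes and tags are misaligned")
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("geometry codes must be distinct")
        if self.noise_transform.shape != (self.latent.shape[1],) * 2:
            raise ValidationError("noise_transform must be dim x dim")

    @property
    def n_concepts(self) -> int:
        return int(self.latent.shape[0])

    def perturb(self, indices: Sequence[int], sigma: float, rng: np.random.Generator) -> np.ndarray:
        """Unit vectors latent[i] + sigma * (z @ noise_transform), row-normalized."""
        idx = np.asarray(indices, dtype=np.int64)
        z = rng.standard_normal((len(idx), self.latent.shape[1]))
        return l2_normalize(self.latent[idx] + sigma * (z @ self.noise_transform), axis=1)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_geometry(config: SynthConfig) -> ConceptGeometry:
    """Draw one latent direction per concept, uniform on the unit sphere, and
    a shared anisotropic noise transform; semantic tags are assigned
    round-robin from the tag set."""
    rng = _rng(config, _STREAM_GEOMETRY)
    latent = l2_normalize(rng.standard_normal((config.n_concepts, config.dim)), axis=1)
    basis = np.linalg.qr(rng.standard_normal((config.dim, config.dim)))[0]
    scales = np.full(config.dim, 1.0 / np.sqrt(config.dim))
    scales[: config.noisy_dims] *= config.noise_boost
    transform = (basis * scales) @ basis.T  # symmetric: boost along `noisy_dims` axes
    codes = tuple(f"{800000 + i}" for i in range(config.n_concepts))
    tags = tuple(config.tag_set[i % len(config.tag_set)] for i in range(config.n_concepts))
    return ConceptGeometry(latent=latent, codes=codes, tags=tags, noise_transform=transform)


def inventory_indices(geometry: ConceptGeometry, config: SynthConfig) -> tuple[list[int], list[int]]:
    """Partition concepts into (in-inventory, held-out-for-zero-shot).

    With zero_shot_fraction > 0 the last ceil(fraction * n) concepts are held
    out of the gazetteer and of train/val mentions; test mentions may draw
    from them.
    """
    n = geometry.n_concepts
    n_holdout = int(np.ceil(config.zero_shot_fraction * n)) if config.zero_shot_fraction else 0
    if n_holdout >= n:
        raise ValidationError("zero-shot holdout would consume every concept")
    kept = list(range(n - n_holdout))
    holdout = list(range(n - n_holdout, n))
    return kept, holdout


def generate_gazetteer(
    geometry: ConceptGeometry, config: SynthConfig
) -> tuple[list[GazetteerEntry], np.ndarray]:
    """Per in-inventory concept, emit 1 + Poisson(mean - 1) synonym surfaces
    with planted embeddings l2_normalize(latent + term_noise_sd * noise).

    Returns the entries and the row-aligned planted vector matrix.
    """
    rng = _rng(config, _STREAM_GAZETTEER)
    kept, _ = inventory_indices(geometry, config)
    entries: list[GazetteerEntry] = []
    vectors: list[np.ndarray] = []
    for ci in kept:
        code, tag = geometry.codes[ci], geometry.tags[ci]
        n_syn = 1 + int(rng.poisson(config.synonyms_mean - 1.0))
        planted = geometry.perturb([ci] * n_syn, config.term_noise_sd, rng)
        for j in range(n_syn):
            entries.append(
                GazetteerEntry(
                    code=code,
                    term=f"term {code} s{j}",
                    semantic_tag=tag,
                    language="xx",
                    is_main_term=(j == 0),
                )
            )
            vectors.append(planted[j])
    return entries, np.vstack(vectors)


def generate_mentions(
    geometry: ConceptGeometry, config: SynthConfig, split: str
) -> tuple[list[MentionAnnotation], np.ndarray]:
    """Draw per-concept mention surfaces with planted embeddings
    l2_normalize(latent + mention_noise_sd * noise).

    For the test split, each mention independently swaps its concept for a
    held-out (zero-shot) one with probability ``zero_shot_fraction``.
    """
    counts = {
        "train": config.mentions_per_concept_train,
        "val": config.mentions_per_concept_val,
        "test": config.mentions_per_concept_test,
    }
    if split not in counts:
        raise ValidationError(f"split must be one of {sorted(counts)}, got {split!r}")
    rng = _rng(config, _STREAM_MENTIONS[split])
    kept, holdout = inventory_indices(geometry, config)
    mentions: list[MentionAnnotation] = []
    vectors: list[np.ndarray] = []
    serial = 0
    for ci in kept:
        for _ in range(counts[split]):
            concept = ci
            if split == "test" and holdout and rng.random() < config.zero_shot_fraction:
                concept = holdout[int(rng.integers(len(holdout)))]
            code = geometry.codes[concept]
            text = f"mention {split} {code} m{serial}"
            serial += 1
            vectors.append(geometry.perturb([concept], config.mention_noise_sd, rng)[0])
            mentions.append(
                MentionAnnotation(
                    doc_id=f"synth_{split}",
                    start=0,
                    end=len(text),
                    text=text,
                    label="SINTOMA",
                    codes=(code,),
                )
            )
    return mentions, np.vstack(vectors)


def planted_backend(
    surfaces: Sequence[str], vectors: np.ndarray, *more: tuple[Sequence[str], np.ndarray]
) -> LookupBackend:
    """Build a lookup backend over one or more (surfaces, vectors) blocks."""
    all_surfaces = list(surfaces)
    blocks = [np.asarray(vectors)]
    for extra_surfaces, extra_vectors in more:
        all_surfaces.extend(extra_surfaces)
        blocks.append(np.asarray(extra_vectors))
    return LookupBackend(all_surfaces, np.vstack(blocks))


def planted_training_backend(
    entries: Sequence[GazetteerEntry],
    term_vectors: np.ndarray,
    mentions: Sequence[MentionAnnotation] = (),
    mention_vectors: np.ndarray | None = None,
    tag_lookup: dict[str, str] | None = None,
) -> LookupBackend:
    """Lookup backend covering both raw and tag-suffixed training surfaces,
    so training sets built by :func:`gazelink.kb_io.build_training_set` can be
    embedded with planted vectors."""
    from .kb_io import format_training_term

    tag_lookup = tag_lookup or {}
    surfaces: list[str] = []
    rows: list[np.ndarray] = []

    def register(surface: str, tag: str, vec: np.ndarray) -> None:
        surfaces.append(surface)
        rows.append(vec)
        if tag:
            surfaces.append(format_training_term(surface, tag))
            rows.append(vec)

    for entry, vec in zip(entries, term_vectors):
        register(entry.term, entry.semantic_tag, vec)
    if len(mentions):
        if mention_vectors is None or len(mentions) != mention_vectors.shape[0]:
            raise ValidationError("mentions and mention_vectors are misaligned")
        for mention, vec in zip(mentions, mention_vectors):
            tag = tag_lookup.get(mention.codes[0], "") if mention.codes else ""
            register(mention.text, tag, vec)
    return LookupBackend(surfaces, np.vstack(rows))


@dataclass(frozen=True)
class RecoveryResult:
    init_top1: float
    tuned_top1: float
    loss_trace: tuple[float, ...]

    @property
    def improvement(self) -> float:
        return self.tuned_top1 - self.init_top1


def recovery_run(
    seed: int,
    learning_rate: float = 3e-4,
    epochs: int = 20,
    temperature: float = 0.05,
    config: SynthConfig | None = None,
) -> RecoveryResult:
    """End-to-end linking run on the default generator: build the training
    set, initialize the head from concept centroids, fine-tune on the
    training-set embeddings, and score validation top-1 before and after."""
    from .embedding import embed_terms
    from .head import HeadTrainConfig, finetune, init_head, logits
    from .kb_io import build_training_set

    config = config or SynthConfig(seed=seed)
    geometry = generate_geometry(config)
    entries, term_vectors = generate_gazetteer(geometry, config)
    train_mentions, train_vectors = generate_mentions(geometry, config, "train")
    val_mentions, val_vectors = generate_mentions(geometry, config, "val")
    tag_lookup = dict(zip(geometry.codes, geometry.tags))
    training = build_training_set(train_mentions, entries, tag_lookup)
    backend = planted_training_backend(
        entries, term_vectors, train_mentions, train_vectors, tag_lookup
    )
    head0 = init_head(training, backend, temperature)

    training_matrix = embed_terms(backend, [t.surface for t in training])
    train_config = HeadTrainConfig(
        learning_rate=learning_rate, epochs=epochs, batch_size=32, seed=seed
    )
    tuned, trace = finetune(head0, training_matrix, [t.code for t in training], train_config)

    def top1(candidate_head) -> float:
        hits = 0
        for mention, vec in zip(val_mentions, val_vectors):
            scores = logits(candidate_head, vec)
            best = int(np.argmax(scores))
            hits += candidate_head.concept_order[best] == mention.codes[0]
        return hits / len(val_mentions)

    return RecoveryResult(
        init_top1=top1(head0), tuned_top1=top1(tuned), loss_trace=tuple(trace)
    )


@dataclass(frozen=True)
class NerCorpusConfig:
    n_docs: int = 20
    mentions_per_doc: int = 5
    n_members: int = 5
    miss_rate: float = 0.2
    false_alarm_rate: float = 0.2
    vocabulary_size: int = 40
    label: str = "SINTOMA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.mentions_per_doc < 1 or self.n_members < 1:
            raise ValidationError("n_docs, mentions_per_doc and n_members must be positive")
        if not (0.0 <= self.miss_rate <= 1.0 and 0.0 <= self.false_alarm_rate <= 1.0):
            raise ValidationError("rates must be in [0, 1]")


def generate_ner_corpus(
    config: NerCorpusConfig,
) -> tuple[list[tuple[str, str]], list[MentionAnnotation], list[set[PredictedSpan]]]:
    """Template documents with mention surfaces at known offsets, plus
    synthetic member predictions derived from gold by independent seeded span
    deletion (miss rate) and spurious-span insertion (false-alarm rate)."""
    rng = np.random.default_rng([config.seed, _STREAM_NER])
    vocabulary = [f"sintoma{i:03d}" for i in range(config.vocabulary_size)]
    documents: list[tuple[str, str]] = []
    gold: list[MentionAnnotation] = []
    for d in range(config.n_docs):
        doc_id = f"doc{d:03d}"
        parts: list[str] = []
        cursor = 0
        for _ in range(config.mentions_per_doc):
            prefix = "El paciente presenta "
            surface = vocabulary[int(rng.integers(len(vocabulary)))]
            suffix = " desde ayer. "
            parts.append(prefix + surface + suffix)
            start = cursor + len(prefix)
            gold.append(
                MentionAnnotation(
                    doc_id=doc_id,
                    start=start,
                    end=start + len(surface),
                    text=surface,
                    label=config.label,
                    codes=(),
                )
            )
            cursor += len(prefix) + len(surface) + len(suffix)
        documents.append((doc_id, "".join(parts)))

    gold_spans = {
        m.doc_id: [g for g in gold if g.doc_id == m.doc_id] for m in gold
    }
    members: list[set[PredictedSpan]] = []
    for _ in range(config.n_members):
        member: set[PredictedSpan] = set()
        for doc_id, text in documents:
            doc_gold = gold_spans.get(doc_id, [])
            for g in doc_gold:
                if rng.random() >= config.miss_rate:
                    member.add(PredictedSpan(doc_id, g.start, g.end, g.label))
            # spurious spans: random non-gold tokens promoted to predictions
            occupied = [(g.start, g.end) for g in doc_gold]
            free_tokens = [
                (s, e)
                for _, s, e in whitespace_tokenize(text)
                if not any(s < ge and e > gs for gs, ge in occupied)
            ]
            n_false = int(rng.binomial(config.mentions_per_doc, config.false_alarm_rate))
            for _ in range(min(n_false, len(free_tokens))):
                s, e = free_tokens[int(rng.integers(len(free_tokens)))]
                member.add(PredictedSpan(doc_id, s, e, config.label))
        members.append(member)
    return documents, gold, members


__all__ = [
    "DEFAULT_TAGS",
    "SynthConfig",
    "ConceptGeometry",
    "NerCorpusConfig",
    "RecoveryResult",
    "recovery_run",
    "generate_geometry",
    "inventory_indices",
    "generate_gazetteer",
    "generate_mentions",
    "generate_ner_corpus",
    "planted_backend",
    "planted_training_backend",
]
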