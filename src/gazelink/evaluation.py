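"""Scoring: strict-span NER precision/recall/F1 and top-k linking accuracy.

Top-k accuracy judges a mention correct at k when its first gold code (the
canonical one for composite mentions) appears among the first k candidate
codes; NER matching is exact on (doc_id, start, end, label) with micro
(global-count) averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

from .errors import ValidationError
from .ner_ensemble import PredictedSpan
from .retrieval import CandidateList

DEFAULT_KS = (1, 5, 25, 50, 100, 200)


@dataclass(frozen=True)
class PRFReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class TopKReport:
    ks: tuple[int, ...]
    accuracy: Mapping[int, float]
    n_evaluated: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ks", tuple(self.ks))
        object.__setattr__(self, "accuracy", dict(self.accuracy))
        if self.n_evaluated <= 0:
            raise ValidationError("n_evaluated must be positive")
        accs = [self.accuracy[k] for k in sorted(self.ks)]
        if any(b < a - 1e-12 for a, b in zip(accs, accs[1:])):
            raise ValidationError("top-k accuracy must be non-decreasing in k")


def ner_prf(gold: Set[PredictedSpan], pred: Set[PredictedSpan]) -> PRFReport:
    """Micro precision/recall/F1 under exact span-and-label matching.

    An empty denominator yields precision (or recall) 1.0 by convention.
    """
    gold, pred = set(gold), set(pred)
    tp = len(gold & pred)
    fp = len(pred - gold)
    fn = len(gold - pred)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return PRFReport(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


def _first_codes(gold: Sequence[Sequence[str]]) -> list[str]:
    firsts = []
    for i, codes in enumerate(gold):
        if not codes:
            raise ValidationError(f"gold code list at position {i} is empty")
        firsts.append(codes[0])
    return firsts


def topk_accuracy(
    gold: Sequence[Sequence[str]],
    candidates: Sequence[CandidateList],
    ks: Sequence[int] = DEFAULT_KS,
) -> TopKReport:
    """Fraction of mentions whose first gold code is within the top k
    candidates, for each k. Candidate lists shorter than k are judged on the
    items they have."""
    if len(gold) != len(candidates):
        raise ValidationError(
            f"{len(gold)} gold lists vs {len(candidates)} candidate lists"
        )
    firsts = _first_codes(gold)
    n = len(gold)
    accuracy = {}
    for k in ks:
        if k < 1:
            raise ValidationError(f"k must be >= 1, got {k}")
        hits = sum(1 for g, c in zip(firsts, candidates) if g in c.codes[:k])
        accuracy[k] = hits / n
    return TopKReport(ks=tuple(ks), accuracy=accuracy, n_evaluated=n)


def per_tag_accuracy(
    gold: Sequence[Sequence[str]],
    candidates: Sequence[CandidateList],
    tags: Sequence[str],
    k: int,
) -> dict[str, tuple[float, int]]:
    """Top-k accuracy within each semantic-tag group (literal string grouping);
    returns tag -> (accuracy, group size). Empty groups are omitted."""
    if not (len(gold) == len(candidates) == len(tags)):
        raise ValidationError("gold, candidates and tags must be aligned")
    firsts = _first_codes(gold)
    groups: dict[str, list[int]] = {}
    for i, tag in enumerate(tags):
        groups.setdefault(tag, []).append(i)
    out: dict[str, tuple[float, int]] = {}
    for tag, idxs in groups.items():
        hits = sum(1 for i in idxs if firsts[i] in candidates[i].codes[:k])
        out[tag] = (hits / len(idxs), len(idxs))
    return out


__all__ = ["DEFAULT_KS", "PRFReport", "TopKReport", "ner_prf", "topk_accuracy", "per_tag_accuracy"]
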