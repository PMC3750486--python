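"""Train/test splitting, threshold classification, and AUC evaluation.

Enriched reads are split 7:3 into training and test sets, matched by
uniform random negative reads (the SELEX starting pool covers all words of
the read length evenly, so uniform sequences are the appropriate null).
Read classification uses the threshold that maximises accuracy on the
training scores, with normal-approximation confidence intervals on the test
accuracy.  Longer ChIP-seq-style sequences are scored the same way and
summarised by the Mann-Whitney AUC with a Hanley-McNeil interval, since a
read-level threshold does not transfer to longer sequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence as Seq

import numpy as np
from scipy.stats import norm, rankdata

from .model import KmerModel
from .sequences import clean_sequence

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class DegenerateLabelsError(ValueError):
    """Threshold optimisation requires both classes."""


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition parameters (default 7:3)."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class EvalResult:
    """A point estimate (accuracy or AUC) with its 95% confidence interval."""

    metric: Literal["accuracy", "auc"]
    value: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    threshold: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def split_reads(reads: list[str], spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive, seed-reproducible train/test partition.

    The training set has round(n * train_fraction) reads.
    """
    n = len(reads)
    if n < 2:
        raise ValueError("need at least 2 reads to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(n * spec.train_fraction))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    return [reads[i] for i in train_idx], [reads[i] for i in test_idx]


def generate_random_reads(
    n: int, length: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """n i.i.d. uniform sequences over {A, C, G, T} of the given length."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in _BASES[codes]]


def optimal_threshold(
    scores: Seq[float], labels: Seq[int]
) -> tuple[float, float]:
    """Threshold maximising accuracy of the rule ``score >= t => positive``.

    Candidate thresholds are the minimum score (everything positive), the
    midpoints between adjacent distinct scores, and just above the maximum
    (everything negative).  Among equally accurate candidates the lowest
    threshold is returned, so a separable instance yields the midpoint of
    the separating gap.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    if labels.min() == labels.max():
        raise DegenerateLabelsError("both classes required to pick a threshold")
    u = np.unique(scores)
    # pos_ge[j]: positives with score >= u[j]; neg_lt[j]: negatives below u[j]
    order = np.searchsorted(u, scores)
    n = len(scores)
    pos_at = np.bincount(order[labels == 1], minlength=len(u))
    neg_at = np.bincount(order[labels == 0], minlength=len(u))
    pos_ge = np.cumsum(pos_at[::-1])[::-1]
    neg_lt = np.concatenate([[0], np.cumsum(neg_at)[:-1]])
    candidates = np.concatenate([[u[0]], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    correct = np.concatenate(
        [[pos_ge[0] + neg_lt[0]], pos_ge[1:] + neg_lt[1:], [neg_at.sum()]]
    )
    best = int(np.argmax(correct))
    return float(candidates[best]), float(correct[best] / n)


def classification_accuracy(
    scores: Seq[float], labels: Seq[int], threshold: float
) -> float:
    """Accuracy of ``score >= threshold => positive`` (ties positive)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    return float(np.mean(pred == labels))


def accuracy_ci(
    n_correct: int, n_total: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Normal-approximation (Wald) interval for a classification accuracy."""
    if not 0 <= n_correct <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_correct <= n_total, n_total >= 1")
    p = n_correct / n_total
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n_total)
    return p, float(max(0.0, p - half)), float(min(1.0, p + half))


def auc(scores_pos: Seq[float], scores_neg: Seq[float]) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs won, ties count 1/2."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def auc_ci_mann_whitney(
    auc_value: float, n_pos: int, n_neg: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation interval for the AUC.

    Uses the exponential-distribution approximation Q1 = A/(2-A),
    Q2 = 2A^2/(1+A) for the variance of the Mann-Whitney statistic.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    a = float(auc_value)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    var = max(var, 0.0)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def accuracy_result(
    scores_pos: Seq[float], scores_neg: Seq[float], threshold: float
) -> EvalResult:
    """Accuracy of the thresholded classifier on a labelled test set,
    with a normal-approximation 95% interval."""
    pos = np.asarray(scores_pos, dtype=np.float64)
    neg = np.asarray(scores_neg, dtype=np.float64)
    n_correct = int((pos >= threshold).sum() + (neg < threshold).sum())
    n_total = len(pos) + len(neg)
    p, lo, hi = accuracy_ci(n_correct, n_total)
    return EvalResult("accuracy", p, lo, hi, len(pos), len(neg), threshold)


def _central_window(s: str, width: int) -> str:
    mid = len(s) // 2
    start = max(0, mid - width // 2)
    return s[start : start + width]


def evaluate_chipseq(
    model: KmerModel,
    positive_seqs: list[str],
    negative_seqs: list[str],
    region_mode: Literal["full", "center"] = "full",
    center_width: int = 100,
    summits: dict[int, int] | None = None,
) -> EvalResult:
    """AUC of the k-mer model on peak vs negative sequences.

    ``center`` mode scores only a fixed-width window around each sequence's
    midpoint (or around a provided summit offset); sequences shorter than
    the window are skipped with a warning.  The AUC interval is the
    Mann-Whitney (Hanley-McNeil) 95% interval.
    """
    if not positive_seqs or not negative_seqs:
        raise ValueError("positive and negative sequence sets must be non-empty")

    def prepare(seqs: list[str], offset_base: int) -> list[str]:
        if region_mode == "full":
            return [clean_sequence(s) for s in seqs]
        out = []
        for i, s in enumerate(seqs):
            s = clean_sequence(s)
            if len(s) < center_width:
                logger.warning(
                    "sequence %d shorter than center window (%d < %d); skipped",
                    offset_base + i, len(s), center_width,
                )
                continue
            if summits is not None and (offset_base + i) in summits:
                mid = summits[offset_base + i]
                start = min(max(0, mid - center_width // 2), len(s) - center_width)
                out.append(s[start : start + center_width])
            else:
                out.append(_central_window(s, center_width))
        return out

    pos = prepare(positive_seqs, 0)
    neg = prepare(negative_seqs, len(positive_seqs))
    if not pos or not neg:
        raise ValueError("all sequences were shorter than the center window")
    scores_pos = model.score_sequences(pos)
    scores_neg = model.score_sequences(neg)
    a = auc(scores_pos, scores_neg)
    lo, hi = auc_ci_mann_whitney(a, len(pos), len(neg))
    return EvalResult("auc", a, lo, hi, len(pos), len(neg))
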