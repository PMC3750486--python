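"""k-mer feature selection.

Three strategies for choosing which k-mers enter the linear model:

* most frequent — highest total count across bound and unbound reads;
* most enriched — highest difference or fold change between bound and
  unbound counts from the k-mer table;
* wrapper selection — greedy backward elimination guided by 10-fold
  cross-validated classification accuracy inside the training set.  At each
  step the k-mer whose removal yields the best (or least bad) CV accuracy
  is dropped.  The held-out test set is never seen here, which avoids
  selection bias in the final performance estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.model_selection import StratifiedKFold

from .evaluate import classification_accuracy, optimal_threshold
from .model import DEFAULT_RIDGE, build_design_matrix
from .sequences import KmerSpec, KmerTable, kmer_sort_key

logger = logging.getLogger(__name__)

SelectionCriterion = Literal["frequency", "difference", "fold_change"]


def select_top(
    table: KmerTable,
    criterion: SelectionCriterion,
    n: int,
    pseudocount: float = 1.0,
) -> list[str]:
    """The top-n k-mers of the table under the given ranking.

    frequency = count_bound + count_unbound; difference = count_bound -
    count_unbound; fold_change = (count_bound + c) / (count_unbound + c)
    with pseudocount c (default 1) so zero unbound counts are defined.
    Ties break deterministically by (k, lexicographic).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if criterion == "frequency":
        score = table.frequency
    elif criterion == "difference":
        score = table.difference
    elif criterion == "fold_change":
        score = lambda w: table.fold_change(w, pseudocount)  # noqa: E731
    else:
        raise ValueError(f"unknown criterion: {criterion}")
    if n > len(table):
        logger.warning(
            "requested %d k-mers but table has only %d; returning all", n, len(table)
        )
        n = len(table)
    ranked = sorted(table.entries, key=lambda w: (-score(w), kmer_sort_key(w)))
    return ranked[:n]


@dataclass
class SelectionTrajectory:
    """Record of a backward-elimination run.

    ``steps`` holds one (kmer_removed, remaining_size, cv_accuracy) triple
    per elimination; remaining_size decreases by exactly one per step.
    """

    start_kmers: tuple[str, ...]
    steps: list[tuple[str, int, float]]
    start_cv_accuracy: float

    def kmers_at(self, size: int) -> list[str]:
        """The surviving k-mer set (in start order) after eliminating down
        to ``size`` features."""
        if not len(self.start_kmers) >= size >= self.final_size:
            raise ValueError(f"size must be in [{self.final_size}, {len(self.start_kmers)}]")
        removed = {w for w, _, _ in self.steps[: len(self.start_kmers) - size]}
        return [w for w in self.start_kmers if w not in removed]

    @property
    def final_size(self) -> int:
        return self.steps[-1][1] if self.steps else len(self.start_kmers)

    @property
    def final_kmers(self) -> list[str]:
        return self.kmers_at(self.final_size)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": i + 1, "removed_kmer": w, "remaining_size": m, "cv_accuracy": a}
            for i, (w, m, a) in enumerate(self.steps)
        ]
        return pd.DataFrame(
            rows, columns=["step", "removed_kmer", "remaining_size", "cv_accuracy"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _CVScorer:
    """Mean k-fold CV accuracy of the ridge model restricted to a feature
    subset, computed from per-fold Gram matrices so candidate subsets are
    cheap to evaluate."""

    def __init__(
        self,
        A: np.ndarray,
        b: np.ndarray,
        folds: int,
        ridge_lambda: float,
        seed: int,
    ) -> None:
        self.ridge = ridge_lambda
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        self.fold_data = []
        for tr, va in skf.split(A, b):
            A_tr, A_va = A[tr], A[va]
            G = A_tr.T @ A_tr
            c = A_tr.T @ b[tr]
            self.fold_data.append((A_tr, b[tr], A_va, b[va], G, c))

    def score(self, cols: np.ndarray) -> float:
        accs = []
        for A_tr, b_tr, A_va, b_va, G, c in self.fold_data:
            Gs = G[np.ix_(cols, cols)].copy()
            Gs[np.diag_indices_from(Gs)] += self.ridge
            try:
                x = scipy.linalg.solve(Gs, c[cols], assume_a="pos")
            except scipy.linalg.LinAlgError:
                x = np.linalg.lstsq(Gs, c[cols], rcond=None)[0]
            thr, _ = optimal_threshold(A_tr[:, cols] @ x, b_tr)
            accs.append(classification_accuracy(A_va[:, cols] @ x, b_va, thr))
        return float(np.mean(accs))


def cv_backward_eliminate(
    bound: list[str],
    unbound: list[str],
    start_kmers: list[str],
    folds: int = 10,
    min_size: int = 1,
    spec: KmerSpec | None = None,
    ridge_lambda: float = DEFAULT_RIDGE,
    seed: int = 0,
) -> SelectionTrajectory:
    """Greedy backward elimination by cross-validated accuracy.

    Starting from ``start_kmers``, repeatedly remove the k-mer whose removal
    gives the highest mean CV accuracy (ties: the lexicographically last
    candidate), down to ``min_size`` features.  Folds are stratified by the
    bound/unbound label and fixed by ``seed``; the per-fold classification
    threshold is re-optimised on each fold's training part only.  All
    evaluation happens inside the (bound, unbound) data passed in — callers
    keep their test set away from this function.
    """
    start_kmers = list(start_kmers)
    if not start_kmers:
        raise ValueError("start_kmers must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min_size < 1 or len(start_kmers) < min_size:
        raise ValueError("need 1 <= min_size <= len(start_kmers)")
    spec = spec or KmerSpec(tuple(sorted({len(w) for w in start_kmers})))

    reads = list(bound) + list(unbound)
    b = np.concatenate([np.ones(len(bound)), np.zeros(len(unbound))])
    A = build_design_matrix(reads, start_kmers, spec).toarray()
    scorer = _CVScorer(A, b, folds, ridge_lambda, seed)

    active = list(range(len(start_kmers)))
    start_cv = scorer.score(np.array(active))
    steps: list[tuple[str, int, float]] = []
    while len(active) > min_size:
        best_acc, best_j = -1.0, None
        for j in active:
            remaining = np.array([i for i in active if i != j])
            acc = scorer.score(remaining)
            # ties: remove the lexicographically last k-mer
            if acc > best_acc or (
                acc == best_acc and start_kmers[j] > start_kmers[best_j]
            ):
                best_acc, best_j = acc, j
        active.remove(best_j)
        steps.append((start_kmers[best_j], len(active), best_acc))
    return SelectionTrajectory(
        start_kmers=tuple(start_kmers), steps=steps, start_cv_accuracy=start_cv
    )
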