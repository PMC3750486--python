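"""High-level training/evaluation pipelines shared by the CLI and scripts.

The canonical SELEX workflow: split the enriched reads 7:3 into training
and test sets, generate uniform random negatives matched in number to each
set, pick k-mers from the training k-mer table, fit affinities, optimise
the classification threshold on training scores, and report test accuracy
with its confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import (
    EvalResult,
    SplitSpec,
    accuracy_result,
    generate_random_reads,
    optimal_threshold,
    split_reads,
)
from .model import DEFAULT_RIDGE, KmerModel, build_design_matrix, fit_affinities, sort_kmers
from .selection import SelectionCriterion, select_top
from .sequences import KmerSpec, build_kmer_table


@dataclass
class TrainReport:
    """Everything a training run produced, for reporting and re-scoring."""

    model: KmerModel
    threshold: float
    train_accuracy: float
    test_result: EvalResult
    train_bound: list[str]
    test_bound: list[str]
    train_unbound: list[str]
    test_unbound: list[str]


def fit_kmer_classifier(
    train_bound: list[str],
    train_unbound: list[str],
    kmers: list[str],
    spec: KmerSpec,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> tuple[KmerModel, float, float]:
    """Fit affinities on a labelled training set and optimise the threshold
    on the training scores.  Returns (model, threshold, train accuracy)."""
    reads = list(train_bound) + list(train_unbound)
    b = np.concatenate([np.ones(len(train_bound)), np.zeros(len(train_unbound))])
    A = build_design_matrix(reads, kmers, spec)
    model = fit_affinities(A, b, ridge_lambda, spec)
    scores = np.asarray(A.matrix @ model.affinities)
    thr, train_acc = optimal_threshold(scores, b)
    return model, thr, train_acc


def evaluate_classifier(
    model: KmerModel, threshold: float, test_bound: list[str], test_unbound: list[str]
) -> EvalResult:
    """Test accuracy of a trained, thresholded model with its 95% CI."""
    return accuracy_result(
        model.score_sequences(test_bound),
        model.score_sequences(test_unbound),
        threshold,
    )


def train_on_selex(
    bound_reads: list[str],
    spec: KmerSpec | None = None,
    n_kmers: int = 100,
    criterion: SelectionCriterion = "frequency",
    ridge_lambda: float = DEFAULT_RIDGE,
    seed: int = 0,
    unbound_reads: list[str] | None = None,
) -> TrainReport:
    """The full SELEX pipeline on one set of enriched reads.

    Splits 7:3, draws matched uniform negatives for both halves (unless an
    explicit unbound read set is supplied, which is then split the same
    way), selects the top ``n_kmers`` by ``criterion`` from the training
    table, fits, and evaluates on the held-out reads.
    """
    spec = spec or KmerSpec()
    split = SplitSpec(train_fraction=0.7, seed=seed)
    train_bound, test_bound = split_reads(bound_reads, split)
    read_length = len(bound_reads[0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    if unbound_reads is None:
        train_unbound = generate_random_reads(len(train_bound), read_length, rng)
        test_unbound = generate_random_reads(len(test_bound), read_length, rng)
    else:
        train_unbound, test_unbound = split_reads(unbound_reads, split)
    table = build_kmer_table(train_bound, train_unbound, spec)
    kmers = sort_kmers(select_top(table, criterion, n_kmers))
    model, thr, train_acc = fit_kmer_classifier(
        train_bound, train_unbound, kmers, spec, ridge_lambda
    )
    test_result = evaluate_classifier(model, thr, test_bound, test_unbound)
    return TrainReport(
        model=model,
        threshold=thr,
        train_accuracy=train_acc,
        test_result=test_result,
        train_bound=train_bound,
        test_bound=test_bound,
        train_unbound=train_unbound,
        test_unbound=test_unbound,
    )
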