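"""Splitting, thresholds, confidence intervals, AUC and peak evaluation."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import oracle_auc, oracle_best_accuracy
from kmerselex import (
    KmerModel,
    KmerSpec,
    SplitSpec,
    accuracy_ci,
    auc,
    auc_ci_mann_whitney,
    evaluate_chipseq,
    generate_random_reads,
    optimal_threshold,
    split_reads,
)
from kmerselex.evaluate import DegenerateLabelsError


class TestSplit:
    def test_seven_three_ratio(self):
        reads = generate_random_reads(10, 14, seed=1)
        train, test = split_reads(reads, SplitSpec(0.7, seed=1))
        assert len(train) == 7 and len(test) == 3

    def test_partition_exhaustive_and_disjoint(self):
        reads = generate_random_reads(37, 14, seed=3)
        train, test = split_reads(reads, SplitSpec(0.7, seed=9))
        assert sorted(train + test) == sorted(reads)
        assert not set(train) & set(test)

    def test_seed_reproducible(self):
        reads = generate_random_reads(20, 14, seed=3)
        assert split_reads(reads, SplitSpec(0.7, 5)) == split_reads(reads, SplitSpec(0.7, 5))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(1.0, 0)


class TestRandomReads:
    def test_shape_and_alphabet(self):
        reads = generate_random_reads(5, 14, seed=0)
        assert len(reads) == 5
        assert all(len(r) == 14 and set(r) <= set("ACGT") for r in reads)

    def test_uniform_base_frequencies(self):
        reads = generate_random_reads(20000, 14, seed=11)
        joined = "".join(reads)
        for b in "ACGT":
            assert joined.count(b) / len(joined) == pytest.approx(0.25, abs=0.01)

    def test_seed_reproducible(self):
        assert generate_random_reads(10, 14, 7) == generate_random_reads(10, 14, 7)


class TestOptimalThreshold:
    def test_separable_midpoint(self):
        thr, acc = optimal_threshold([3, 2, 1, 0], [1, 1, 0, 0])
        assert thr == 1.5 and acc == 1.0

    def test_identical_scores(self):
        thr, acc = optimal_threshold([1.0, 1.0], [1, 0])
        assert acc == 0.5

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            thr, acc = optimal_threshold(scores, labels)
            assert acc == pytest.approx(oracle_best_accuracy(scores, labels))
            # the returned threshold realises the returned accuracy
            realized = np.mean((scores >= thr).astype(int) == labels)
            assert realized == pytest.approx(acc)

    def test_beats_prevalence(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(25), np.zeros(15)].astype(int)
        _, acc = optimal_threshold(scores, labels)
        assert acc >= 25 / 40

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            optimal_threshold([1.0, 2.0], [1, 1])


class TestAccuracyCI:
    def test_closed_form(self):
        z = norm.ppf(0.975)
        p, lo, hi = accuracy_ci(50, 100)
        assert p == 0.5
        assert lo == pytest.approx(0.5 - z * np.sqrt(0.25 / 100))
        assert hi == pytest.approx(0.5 + z * np.sqrt(0.25 / 100))

    def test_zero_variance_edge(self):
        assert accuracy_ci(100, 100) == (1.0, 1.0, 1.0)

    def test_width_shrinks_with_n(self):
        widths = [
            accuracy_ci(n // 2, n)[2] - accuracy_ci(n // 2, n)[1]
            for n in (10, 100, 1000, 100000)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestAUC:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [([2, 3], [0, 1], 1.0), ([3, 1], [2, 0], 0.75), ([1], [1], 0.5)],
    )
    def test_examples(self, pos, neg, expected):
        assert auc(pos, neg) == pytest.approx(expected)

    def test_matches_pair_enumeration(self, rng):
        for _ in range(30):
            pos = rng.choice([0.0, 1.0, 2.5, 3.0], size=int(rng.integers(1, 10)))
            neg = rng.choice([0.0, 1.0, 2.5, 3.0], size=int(rng.integers(1, 10)))
            assert auc(pos, neg) == pytest.approx(oracle_auc(pos, neg))

    def test_reversal_identity(self, rng):
        pos = rng.choice([0.0, 1.0, 2.0], size=20)
        neg = rng.choice([0.0, 1.0, 2.0], size=15)
        assert auc(pos, neg) + auc(neg, pos) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        pos, neg = rng.normal(1, 1, 25), rng.normal(0, 1, 25)
        assert auc(np.exp(pos), np.exp(neg)) == pytest.approx(auc(pos, neg))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestAUCCI:
    def test_hand_computed_hanley_mcneil(self):
        a, n1, n2 = 0.8, 50, 40
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
        z = norm.ppf(0.975)
        lo, hi = auc_ci_mann_whitney(a, n1, n2)
        assert lo == pytest.approx(a - z * np.sqrt(var))
        assert hi == pytest.approx(a + z * np.sqrt(var))

    def test_symmetric_about_half(self):
        lo, hi = auc_ci_mann_whitney(0.5, 200, 200)
        assert (0.5 - lo) == pytest.approx(hi - 0.5)

    def test_width_shrinks_with_n(self):
        w = [
            np.diff(auc_ci_mann_whitney(0.7, n, n))[0]
            for n in (25, 50, 100, 200)
        ]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_perfect_auc_degenerate(self):
        assert auc_ci_mann_whitney(1.0, 30, 30) == (1.0, 1.0)


class TestEvaluateChipseq:
    def _model(self):
        return KmerModel(("ACGTCA",), np.array([1.0]), spec=KmerSpec((6,)))

    def test_perfect_separation(self, rng):
        model = self._model()
        pos = ["ACGTCA" + generate_random_reads(1, 44, rng)[0] for _ in range(20)]
        neg = [s.replace("ACGTCA", "ACCCCA").replace("TGACGT", "TGGGGT")
               for s in generate_random_reads(20, 50, rng)]
        res = evaluate_chipseq(model, pos, neg)
        assert res.value == 1.0 and res.metric == "auc"

    def test_zero_model_ties(self, rng):
        model = KmerModel(("ACGTCA",), np.array([0.0]), spec=KmerSpec((6,)))
        pos = generate_random_reads(15, 60, rng)
        neg = generate_random_reads(15, 60, rng)
        res = evaluate_chipseq(model, pos, neg)
        assert res.value == 0.5

    def test_center_equal_to_full_when_width_covers(self, rng):
        model = self._model()
        pos = generate_random_reads(10, 40, rng)
        neg = generate_random_reads(10, 40, rng)
        full = evaluate_chipseq(model, pos, neg, region_mode="full")
        center = evaluate_chipseq(model, pos, neg, region_mode="center",
                                  center_width=40)
        assert center.value == full.value

    def test_short_sequences_skipped(self, rng, caplog):
        model = self._model()
        pos = generate_random_reads(5, 120, rng) + ["ACGTACGT"]
        neg = generate_random_reads(5, 120, rng)
        res = evaluate_chipseq(model, pos, neg, region_mode="center", center_width=100)
        assert res.n_pos == 5
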